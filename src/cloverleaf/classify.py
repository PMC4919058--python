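"""Classification of stem pair-state transitions (the CSBPS taxonomy).

A CSBPS ("change of sequence in a base pair of a stem") is any difference
between the same stem pair in two homologous tRNAs.  The taxonomy:

* **HCBC** (hemi-compensatory base change): exactly one base of the pair is
  substituted and pairing survives at both endpoints, typically via a G/T
  wobble (e.g. A-T vs G.T).
* **FCBC** (fully compensatory base change): both bases substituted, both
  endpoints paired.  Type I keeps the purine-pyrimidine orientation
  (A-T vs G-C); type II flips it (T-A vs A-T), which requires passage
  through a mismatch intermediate or a simultaneous double substitution.
* **Mismatch**: the derived pair is neither Watson-Crick nor wobble.  With a
  direction (ancestor -> descendant) this splits into mismatch gain and
  mismatch resolution.

Wobble-to-wobble double changes (G.T -> T.G) are kept apart as
``other_double``: they change both bases and stay paired, but flipping the
wobble is not a named compensatory category and counting it as an FCBC would
inflate that tally.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    EventClass,
    EventKind,
    FcbcType,
    IndeterminateStateError,
    PairCategory,
    PairState,
    Side,
    StemLayout,
    orientation_flip,
)

__all__ = [
    "classify_transition",
    "unordered_kind",
    "compare_sequences_pairwise",
    "apply_boundary_filter",
]

logger = logging.getLogger(__name__)


def _changed_side(a: PairState, b: PairState) -> Side:
    c5 = a.base5 != b.base5
    c3 = a.base3 != b.base3
    if c5 and c3:
        return Side.BOTH
    if c5:
        return Side.FIVE_PRIME
    if c3:
        return Side.THREE_PRIME
    return Side.NONE


def classify_transition(from_state: PairState, to_state: PairState) -> EventClass:
    """Assign exactly one :class:`~cloverleaf.model.EventClass` to an ordered
    pair-state transition.

    The direction matters only for telling mismatch gain from mismatch
    resolution; HCBC/FCBC/other_double verdicts are symmetric.

    Raises
    ------
    IndeterminateStateError
        If either state carries an ambiguity code or gap; callers skip the
        comparison and log the reason.
    """
    if not (from_state.determinate and to_state.determinate):
        raise IndeterminateStateError(
            f"cannot classify transition with indeterminate state: "
            f"{from_state} -> {to_state}"
        )
    side = _changed_side(from_state, to_state)
    if side is Side.NONE:
        return EventClass(EventKind.NO_CHANGE, changed_side=Side.NONE)
    if to_state.category is PairCategory.MISMATCH:
        return EventClass(EventKind.MISMATCH_GAIN, changed_side=side)
    if from_state.category is PairCategory.MISMATCH:
        return EventClass(EventKind.MISMATCH_RESOLUTION, changed_side=side)
    # both endpoints paired (Watson-Crick or wobble) from here on
    if side is not Side.BOTH:
        return EventClass(EventKind.HCBC, changed_side=side)
    if (
        from_state.category is PairCategory.WOBBLE
        and to_state.category is PairCategory.WOBBLE
    ):
        return EventClass(EventKind.OTHER_DOUBLE, changed_side=Side.BOTH)
    fcbc_type = FcbcType.II if orientation_flip(from_state, to_state) else FcbcType.I
    return EventClass(EventKind.FCBC, fcbc_type=fcbc_type, changed_side=Side.BOTH)


#: Map a directed kind onto the undirected class used in interspecific
#: figure-style tallies: gain and resolution both read "mismatch".
_UNORDERED = {
    EventKind.MISMATCH_GAIN: "mismatch",
    EventKind.MISMATCH_RESOLUTION: "mismatch",
    EventKind.HCBC: "hcbc",
    EventKind.FCBC: "fcbc",
    EventKind.OTHER_DOUBLE: "other_double",
    EventKind.NO_CHANGE: "no_change",
}


def unordered_kind(event_class: EventClass) -> str:
    """The direction-free class name (``fcbc`` / ``hcbc`` / ``mismatch`` /
    ``other_double``) of a classified transition."""
    return _UNORDERED[event_class.kind]


def compare_sequences_pairwise(
    stem_set, taxon_a: str, taxon_b: str
) -> List[Tuple[Tuple[str, int], EventClass]]:
    """Compare two taxa of an :class:`~cloverleaf.io.OrthologousStemSet`
    pair by pair (the intraspecific screening mode).

    Returns one ``((stem, pair_index), EventClass)`` entry per annotated pair
    where the two states differ and both are determinate and present for
    both taxa.  Because this mode has no ancestor/descendant direction,
    interpret the kinds through :func:`unordered_kind`.
    """
    for taxon in (taxon_a, taxon_b):
        if taxon not in stem_set.pair_states:
            raise KeyError(f"taxon {taxon!r} not in alignment of {stem_set.trna_id}")
    out: List[Tuple[Tuple[str, int], EventClass]] = []
    for pair_key in stem_set.layout.pairs:
        sa = stem_set.pair_states[taxon_a].get(pair_key)
        sb = stem_set.pair_states[taxon_b].get(pair_key)
        if sa is None or sb is None:  # pair absent for a taxon
            continue
        if not (sa.determinate and sb.determinate):
            logger.debug(
                "%s %s: skipped indeterminate pair %s vs %s",
                stem_set.trna_id, pair_key, sa, sb,
            )
            continue
        verdict = classify_transition(sa, sb)
        if verdict.kind is not EventKind.NO_CHANGE:
            out.append((pair_key, verdict))
    return out


def apply_boundary_filter(
    events: Sequence,
    layout: StemLayout,
    lengths_vary: Optional[Dict[str, bool]] = None,
) -> List:
    """Drop mismatch events sitting on the arm/loop boundary of
    variable-length stems.

    When the DHU or TPsiC arm length varies across taxa, a "mismatch" at the
    loop-adjacent terminal pair of that arm is an artefact of aligning stems
    of different depths rather than a genuine pairing disruption, so
    mismatch_gain/mismatch_resolution events at that pair are removed.  All
    other events (HCBC/FCBC anywhere, mismatches elsewhere) pass through.

    Parameters
    ----------
    events
        Objects with ``stem``, ``pair_index`` and ``event_class`` attributes
        (e.g. :class:`~cloverleaf.mapping.CSBPSEvent`).
    layout
        The stem layout whose terminal DHU/TPsiC pairs define the boundary.
    lengths_vary
        Per-stem flag; only stems flagged True have their boundary pair
        filtered.  Defaults to no stems varying (no-op).
    """
    lengths_vary = lengths_vary or {}
    by_stem = dict(layout.stems)
    boundary = {
        stem: max(by_stem[stem])
        for stem in ("dh", "tp")
        if by_stem.get(stem) and lengths_vary.get(stem, False)
    }
    kept = []
    for ev in events:
        is_mismatch = ev.event_class.kind in (
            EventKind.MISMATCH_GAIN,
            EventKind.MISMATCH_RESOLUTION,
        )
        if is_mismatch and boundary.get(ev.stem) == ev.pair_index:
            continue
        kept.append(ev)
    return kept
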