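"""Ancestral pair-state reconstruction and branch-event extraction.

Each stem pair is reconstructed one nucleotide site at a time (4-state
unordered parsimony), then the two sites are composed into a pair state per
node.  Reconstructing the pair as a single 16-state character would charge a
double substitution one step and silently fold fully compensatory changes
into the single-change count; per-site reconstruction keeps the two
substitutions of an FCBC visible as two steps.

The bottom-up pass is Hartigan's counting form of Fitch parsimony, which is
exact for unit-cost unordered characters on trees of any degree and reduces
to the classic Fitch intersection/union rule on binary trees.  Ambiguity
codes enter as candidate sets; fully missing tips contribute a full
{A,C,G,T} set, which leaves the parsimony length unchanged (equivalent to
excluding them).

Ties (nodes whose candidate set has more than one state) are resolved
deterministically — root takes the lexicographically smallest candidate,
children inherit the parent's state when possible — and counted, so the
sensitivity of downstream tallies to tie-breaking is auditable.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

from .classify import apply_boundary_filter, classify_transition, unordered_kind
from .io import OrthologousStemSet, Phylogeny
from .model import (
    ALPHA_STRAND_TRNAS,
    EventClass,
    EventKind,
    FcbcType,
    IUPAC_SETS,
    PairState,
    Side,
    make_pair_state,
)

__all__ = [
    "CSBPSEvent",
    "SPICRecord",
    "AnnotatedTree",
    "fitch_reconstruct",
    "resolve_node_states",
    "reconstruct_pair_states",
    "extract_branch_events",
    "map_events",
    "summarize_events",
    "EventSummary",
    "build_spic_catalog",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_FULL = frozenset(_BASES)


@dataclass(frozen=True)
class CSBPSEvent:
    """One branch-localised stem pair change.

    The same pair changing on k branches yields k events; tallies therefore
    sum per-branch counts, as in per-node mapping figures.
    """

    trna_id: str
    stem: str
    pair_index: int
    parent_id: str
    child_id: str
    from_state: PairState
    to_state: PairState
    event_class: EventClass
    is_terminal: bool
    retained: bool = True

    @property
    def pair_label(self) -> str:
        return f"{self.pair_index}{self.stem}"


# --- parsimony --------------------------------------------------------------


def _tip_state_set(value) -> FrozenSet[str]:
    """Normalise a tip observation (base, IUPAC code, set, or None) to a
    candidate set; missing observations become the full base set."""
    if value is None:
        return _FULL
    if isinstance(value, (set, frozenset)):
        s = frozenset(value) & _FULL
        return s or _FULL
    sym = str(value).upper().replace("U", "T")
    if sym in IUPAC_SETS:
        s = IUPAC_SETS[sym] & _FULL
        return s or _FULL
    raise ValueError(f"invalid tip state {value!r}")


def fitch_reconstruct(
    phylo: Phylogeny, tip_states: Dict[str, Union[str, Set[str], None]]
) -> Tuple[Dict[str, FrozenSet[str]], int]:
    """Bottom-up unordered parsimony over one alignment column.

    Returns candidate state sets for every node and the minimal number of
    substitutions.  Tips absent from ``tip_states`` (or given gaps/N) are
    treated as uninformative.
    """
    missing = set(phylo.tip_labels) - set(tip_states)
    if missing:
        raise ValueError(f"tips without states: {sorted(missing)}")
    sets: Dict[str, FrozenSet[str]] = {}
    length = 0
    for nid in phylo.postorder_ids():
        if phylo.is_tip(nid):
            sets[nid] = _tip_state_set(tip_states[nid])
        else:
            children = phylo.children(nid)
            votes = Counter()
            for c in children:
                for s in sets[c]:
                    votes[s] += 1
            top = max(votes.values())
            sets[nid] = frozenset(s for s, v in votes.items() if v == top)
            length += len(children) - top
    return sets, length


def resolve_node_states(
    candidate_sets: Dict[str, FrozenSet[str]], phylo: Phylogeny
) -> Tuple[Dict[str, str], int]:
    """Deterministic top-down resolution of candidate sets to one base per
    node.

    The root takes its lexicographically smallest candidate (A<C<G<T); each
    child keeps the parent's state when it is in the child's set, otherwise
    its own lexicographically smallest candidate.  Returns the assignment
    and the number of ambiguous (tied) nodes encountered.
    """
    resolved: Dict[str, str] = {}
    ties = 0
    for nid in phylo.preorder_ids():
        cands = candidate_sets[nid]
        if len(cands) > 1:
            ties += 1
        parent = phylo.parent(nid)
        if parent is None:
            resolved[nid] = min(cands)
        else:
            p_state = resolved[parent]
            resolved[nid] = p_state if p_state in cands else min(cands)
    return resolved, ties


# --- pair-state composition and event extraction ---------------------------


@dataclass
class AnnotatedTree:
    """A phylogeny with a resolved pair state at every node for every stem
    pair of one tRNA."""

    trna_id: str
    phylo: Phylogeny
    # node_states[node_id][(stem, pair_index)] -> PairState or None (absent)
    node_states: Dict[str, Dict[Tuple[str, int], Optional[PairState]]]
    stem_set: OrthologousStemSet
    ties: int = 0
    parsimony_length: int = 0
    skipped_pairs: int = 0


def reconstruct_pair_states(
    stem_set: OrthologousStemSet, phylo: Phylogeny
) -> AnnotatedTree:
    """Reconstruct both nucleotides of every stem pair at every node and
    compose them into per-node pair states.

    Internal nodes always receive determinate composed states; tips keep
    their observed (possibly indeterminate or absent) states so that
    terminal branches with ambiguous data are skipped rather than guessed.
    """
    taxa = set(stem_set.taxa)
    tree_tips = set(phylo.tip_labels)
    missing = taxa - tree_tips
    if missing:
        raise ValueError(
            f"{stem_set.trna_id}: taxa absent from tree: {sorted(missing)}"
        )

    node_states: Dict[str, Dict[Tuple[str, int], Optional[PairState]]] = defaultdict(dict)
    total_ties = 0
    total_length = 0
    skipped = 0

    for slot in stem_set.slots:
        key = (slot.stem, slot.pair_index)
        tips5: Dict[str, Optional[str]] = {}
        tips3: Dict[str, Optional[str]] = {}
        for tip in phylo.tip_labels:
            st = stem_set.pair_states.get(tip, {}).get(key) if tip in taxa else None
            if st is None:
                tips5[tip] = None
                tips3[tip] = None
            else:
                tips5[tip] = st.base5
                tips3[tip] = st.base3
        sets5, len5 = fitch_reconstruct(phylo, tips5)
        sets3, len3 = fitch_reconstruct(phylo, tips3)
        res5, ties5 = resolve_node_states(sets5, phylo)
        res3, ties3 = resolve_node_states(sets3, phylo)
        total_ties += ties5 + ties3
        total_length += len5 + len3

        for nid in phylo.postorder_ids():
            if phylo.is_tip(nid):
                if nid in taxa:
                    st = stem_set.pair_states[nid].get(key)
                    node_states[nid][key] = st
                    if st is not None and not st.determinate:
                        skipped += 1
                else:
                    node_states[nid][key] = None
            else:
                node_states[nid][key] = make_pair_state(res5[nid], res3[nid])

    return AnnotatedTree(
        trna_id=stem_set.trna_id,
        phylo=phylo,
        node_states=dict(node_states),
        stem_set=stem_set,
        ties=total_ties,
        parsimony_length=total_length,
        skipped_pairs=skipped,
    )


def extract_branch_events(
    annotated: AnnotatedTree,
    boundary_filter: bool = True,
    ingroup: Optional[Sequence[str]] = None,
) -> List[CSBPSEvent]:
    """Emit one classified :class:`CSBPSEvent` per (branch, pair) where the
    resolved parent state differs from the child state.

    Branches to tips with indeterminate or absent pairs are skipped (logged).
    With ``ingroup`` given, only branches whose child clade lies entirely
    inside the ingroup are tallied — the branch subtending the ingroup root
    is included, so its events still use the outgroup-informed
    reconstruction.
    """
    phylo = annotated.phylo
    ingroup_set = set(ingroup) if ingroup is not None else None
    events: List[CSBPSEvent] = []
    for parent_id, child_id in phylo.branches():
        if ingroup_set is not None:
            if not phylo.tip_descendants(child_id) <= ingroup_set:
                continue
        for key, child_state in annotated.node_states[child_id].items():
            parent_state = annotated.node_states[parent_id][key]
            if child_state is None or parent_state is None:
                continue
            if not (child_state.determinate and parent_state.determinate):
                logger.debug(
                    "%s %s: skipped indeterminate state on branch %s->%s",
                    annotated.trna_id, key, parent_id, child_id,
                )
                continue
            if (parent_state.base5, parent_state.base3) == (
                child_state.base5, child_state.base3
            ):
                continue
            verdict = classify_transition(parent_state, child_state)
            events.append(
                CSBPSEvent(
                    trna_id=annotated.trna_id,
                    stem=key[0],
                    pair_index=key[1],
                    parent_id=parent_id,
                    child_id=child_id,
                    from_state=parent_state,
                    to_state=child_state,
                    event_class=verdict,
                    is_terminal=phylo.is_tip(child_id),
                )
            )
    if boundary_filter:
        events = apply_boundary_filter(
            events, annotated.stem_set.layout, annotated.stem_set.lengths_vary
        )
    return events


def map_events(
    stem_sets: Union[OrthologousStemSet, Sequence[OrthologousStemSet]],
    phylo: Phylogeny,
    boundary_filter: bool = True,
    ingroup: Optional[Sequence[str]] = None,
) -> List[CSBPSEvent]:
    """Reconstruct and extract events for one or many tRNAs on a shared
    reference tree."""
    if isinstance(stem_sets, OrthologousStemSet):
        stem_sets = [stem_sets]
    events: List[CSBPSEvent] = []
    for ss in stem_sets:
        annotated = reconstruct_pair_states(ss, phylo)
        events.extend(
            extract_branch_events(annotated, boundary_filter=boundary_filter,
                                  ingroup=ingroup)
        )
    return events


# --- tallies ----------------------------------------------------------------


@dataclass
class EventSummary:
    """Global, per-tRNA, per-strand and terminal/internal event tallies.

    ``mismatch`` counts both mismatch gains and resolutions (the undirected
    "mismatch" class of interspecific comparisons); ``other_double`` (e.g.
    wobble-to-wobble flips) is reported separately and excluded from the
    CSBPS total.
    """

    total: int = 0
    fcbc: int = 0
    hcbc: int = 0
    mismatch: int = 0
    other_double: int = 0
    fcbc_type_i: int = 0
    fcbc_type_ii: int = 0
    per_trna: Dict[str, Dict[str, int]] = field(default_factory=dict)
    per_strand: Dict[str, Dict[str, int]] = field(default_factory=dict)
    terminal: Dict[str, int] = field(default_factory=dict)
    internal: Dict[str, int] = field(default_factory=dict)
    terminal_percent: Dict[str, Optional[float]] = field(default_factory=dict)
    # distinct (from,to) transition types per class, in two conventions
    transition_types_directed: Dict[str, int] = field(default_factory=dict)
    transition_types_unordered: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total_csbps": self.total,
            "fcbc": self.fcbc,
            "hcbc": self.hcbc,
            "mismatch": self.mismatch,
            "other_double": self.other_double,
            "fcbc_type_i": self.fcbc_type_i,
            "fcbc_type_ii": self.fcbc_type_ii,
            "per_trna": self.per_trna,
            "per_strand": self.per_strand,
            "terminal": self.terminal,
            "internal": self.internal,
            "terminal_percent": self.terminal_percent,
            "transition_types_directed": self.transition_types_directed,
            "transition_types_unordered": self.transition_types_unordered,
        }


_CLASSES = ("fcbc", "hcbc", "mismatch")


def summarize_events(events: Sequence[CSBPSEvent]) -> EventSummary:
    """Tally classified events: totals by class and FCBC type, per-tRNA and
    per-strand counts, terminal vs internal partition, and distinct
    transition types per class (directed and unordered conventions)."""
    summary = EventSummary()
    per_trna: Dict[str, Counter] = defaultdict(Counter)
    per_strand: Dict[str, Counter] = defaultdict(Counter)
    term = Counter()
    intern = Counter()
    directed: Dict[str, Set] = defaultdict(set)
    unordered: Dict[str, Set] = defaultdict(set)

    for ev in events:
        if not ev.retained or ev.event_class.kind is EventKind.NO_CHANGE:
            continue
        cls = unordered_kind(ev.event_class)
        if cls == "other_double":
            summary.other_double += 1
            continue
        summary.total += 1
        setattr(summary, cls, getattr(summary, cls) + 1)
        if ev.event_class.kind is EventKind.FCBC:
            if ev.event_class.fcbc_type is FcbcType.I:
                summary.fcbc_type_i += 1
            else:
                summary.fcbc_type_ii += 1
        per_trna[ev.trna_id][cls] += 1
        strand = "alpha" if ev.trna_id in ALPHA_STRAND_TRNAS else "beta"
        per_strand[strand][cls] += 1
        (term if ev.is_terminal else intern)[cls] += 1
        duo = (
            (ev.from_state.base5, ev.from_state.base3),
            (ev.to_state.base5, ev.to_state.base3),
        )
        directed[cls].add(duo)
        unordered[cls].add(frozenset(duo))

    summary.per_trna = {
        t: {c: per_trna[t].get(c, 0) for c in _CLASSES} for t in sorted(per_trna)
    }
    summary.per_strand = {
        s: {c: per_strand[s].get(c, 0) for c in _CLASSES}
        for s in ("alpha", "beta")
    }
    summary.terminal = {c: term.get(c, 0) for c in _CLASSES}
    summary.terminal["all"] = sum(term.values())
    summary.internal = {c: intern.get(c, 0) for c in _CLASSES}
    summary.internal["all"] = sum(intern.values())
    for c in (*_CLASSES, "all"):
        tot = summary.terminal[c] + summary.internal[c]
        summary.terminal_percent[c] = (
            round(100.0 * summary.terminal[c] / tot, 2) if tot else None
        )
    summary.transition_types_directed = {c: len(directed[c]) for c in _CLASSES}
    summary.transition_types_unordered = {c: len(unordered[c]) for c in _CLASSES}
    return summary


# --- SPIC catalogue ---------------------------------------------------------


@dataclass
class SPICRecord:
    """A stem position involved in base change: one (tRNA, pair, side)
    location with at least one event anywhere in the tree."""

    trna_id: str
    stem: str
    pair_index: int
    side: str  # five_prime | three_prime | pair_level
    event_counts: Dict[str, int]
    percent_of_spics: float = 0.0
    percent_of_csbps: float = 0.0

    @property
    def classes_observed(self) -> Tuple[str, ...]:
        return tuple(sorted(c for c, n in self.event_counts.items() if n > 0))

    @property
    def n_events(self) -> int:
        return sum(self.event_counts.values())


def _spic_side(ev: CSBPSEvent) -> str:
    if ev.event_class.kind is EventKind.FCBC or ev.event_class.changed_side is Side.BOTH:
        return "pair_level"
    return ev.event_class.changed_side.value


def build_spic_catalog(events: Sequence[CSBPSEvent]) -> List[SPICRecord]:
    """Group events into SPIC records keyed by (tRNA, pair, side).

    HCBC and single-side mismatch events are attributed to the 5' or 3' end
    of the pair; FCBCs and double-change mismatches are pair-level.
    Percentages are relative to the total number of SPICs and to the total
    CSBPS count.
    """
    groups: Dict[Tuple[str, str, int, str], Counter] = defaultdict(Counter)
    total_events = 0
    for ev in events:
        if not ev.retained or ev.event_class.kind is EventKind.NO_CHANGE:
            continue
        cls = unordered_kind(ev.event_class)
        if cls == "other_double":
            continue
        total_events += 1
        groups[(ev.trna_id, ev.stem, ev.pair_index, _spic_side(ev))][cls] += 1

    n_spics = len(groups)
    records = []
    for (trna, stem, idx, side), counts in sorted(groups.items()):
        records.append(
            SPICRecord(
                trna_id=trna,
                stem=stem,
                pair_index=idx,
                side=side,
                event_counts={c: counts.get(c, 0) for c in _CLASSES},
                percent_of_spics=round(100.0 / n_spics, 2) if n_spics else 0.0,
                percent_of_csbps=(
                    round(100.0 * sum(counts.values()) / total_events, 2)
                    if total_events
                    else 0.0
                ),
            )
        )
    return records
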