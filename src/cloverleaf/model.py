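"""Domain types for mitochondrial tRNA stems and base-pair states.

The 22 metazoan mitochondrial tRNAs fold into a cloverleaf whose four
double-helical elements (acceptor, DHU, anticodon and TPsiC stems) are built
from ordered nucleotide pairs.  Everything downstream — classification of
compensatory changes, ancestral mapping, composition statistics — operates on
the small algebra defined here: a pair of bases with a pairing category
(Watson-Crick, G/T wobble, or mismatch) and a purine/pyrimidine orientation.

Bases are stored in the DNA alphabet (T, not U), matching gene-level notation;
readers normalise U to T.  IUPAC ambiguity codes and gaps are carried as
*indeterminate* states rather than rejected, so alignments derived from real
GenBank records load cleanly; analysis stages skip indeterminate pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Tuple

__all__ = [
    "TRNA_NAMES",
    "ALPHA_STRAND_TRNAS",
    "BETA_STRAND_TRNAS",
    "STEM_NAMES",
    "PairCategory",
    "Orientation",
    "PairState",
    "EventKind",
    "FcbcType",
    "Side",
    "EventClass",
    "StemLayout",
    "make_pair_state",
    "canonical_stem_layout",
    "orientation_flip",
    "ALL_DETERMINATE_STATES",
    "IndeterminateStateError",
]

#: The 22 mitochondrial tRNA gene names (one per codon family; Leu and Ser
#: each split into two families).
TRNA_NAMES: Tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)

#: tRNAs encoded on the alpha strand of vertebrate mtDNA (14 genes).
ALPHA_STRAND_TRNAS = frozenset(
    {"trnD", "trnF", "trnG", "trnH", "trnI", "trnK", "trnL1", "trnL2",
     "trnM", "trnR", "trnS1", "trnT", "trnV", "trnW"}
)
#: tRNAs encoded on the complementary beta strand (8 genes).
BETA_STRAND_TRNAS = frozenset(set(TRNA_NAMES) - ALPHA_STRAND_TRNAS)

#: Stem identifiers: acceptor, DHU, anticodon, TPsiC.
STEM_NAMES: Tuple[str, ...] = ("ac", "dh", "an", "tp")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_BASES = "ACGT"

# IUPAC nucleotide codes mapped to the base sets they denote.  Gap characters
# denote "no base" and map to the empty set.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset(), ".": frozenset(),
}

_WATSON_CRICK = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
_WOBBLE = frozenset({("G", "T"), ("T", "G")})


class IndeterminateStateError(ValueError):
    """Raised when an operation requires determinate bases but got an
    ambiguity code or gap."""


class PairCategory(str, Enum):
    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"
    INDETERMINATE = "indeterminate"


class Orientation(str, Enum):
    PUR_PYR = "pur_pyr"
    PYR_PUR = "pyr_pur"
    PUR_PUR = "pur_pur"
    PYR_PYR = "pyr_pyr"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PairState:
    """One stem pair: the 5' base, the 3' base, and derived attributes.

    States are ordered: (G, T) and (T, G) are distinct, because single-base
    changes are attributed to the 5' or 3' end of the pair.
    """

    base5: str
    base3: str
    category: PairCategory
    orientation: Orientation

    @property
    def determinate(self) -> bool:
        return self.category is not PairCategory.INDETERMINATE

    @property
    def paired(self) -> bool:
        """True for Watson-Crick or wobble pairing (secondary structure
        intact)."""
        return self.category in (PairCategory.WATSON_CRICK, PairCategory.WOBBLE)

    def __str__(self) -> str:  # e.g. "A-T", "G.T", "A|A"
        sym = {
            PairCategory.WATSON_CRICK: "-",
            PairCategory.WOBBLE: ".",
            PairCategory.MISMATCH: "|",
            PairCategory.INDETERMINATE: "?",
        }[self.category]
        return f"{self.base5}{sym}{self.base3}"


def _orientation(base5: str, base3: str) -> Orientation:
    if base5 in PURINES:
        return Orientation.PUR_PYR if base3 in PYRIMIDINES else Orientation.PUR_PUR
    return Orientation.PYR_PUR if base3 in PURINES else Orientation.PYR_PYR


def make_pair_state(base5: str, base3: str) -> PairState:
    """Build a :class:`PairState` from two nucleotide symbols.

    Accepts the full IUPAC alphabet plus ``-``/``.`` gaps; ``U`` is normalised
    to ``T`` and case is ignored.  Ambiguity codes and gaps yield an
    indeterminate state (skipped by downstream classification) rather than an
    error.

    Raises
    ------
    ValueError
        If either symbol is not an IUPAC nucleotide or gap code; the message
        names the offending symbol.
    """
    b5 = str(base5).upper().replace("U", "T")
    b3 = str(base3).upper().replace("U", "T")
    for sym in (b5, b3):
        if sym not in IUPAC_SETS:
            raise ValueError(f"not an IUPAC nucleotide or gap symbol: {sym!r}")
    if b5 not in _BASES or b3 not in _BASES:
        return PairState(b5, b3, PairCategory.INDETERMINATE, Orientation.INDETERMINATE)
    duo = (b5, b3)
    if duo in _WATSON_CRICK:
        cat = PairCategory.WATSON_CRICK
    elif duo in _WOBBLE:
        cat = PairCategory.WOBBLE
    else:
        cat = PairCategory.MISMATCH
    return PairState(b5, b3, cat, _orientation(b5, b3))


#: All 16 determinate pair states, in lexicographic (base5, base3) order.
ALL_DETERMINATE_STATES: Tuple[PairState, ...] = tuple(
    make_pair_state(a, b) for a, b in itertools.product(_BASES, _BASES)
)


def orientation_flip(a: PairState, b: PairState) -> bool:
    """True iff the two states' orientations are the pur-pyr / pyr-pur swap
    of each other.

    This is the mark of a type II fully compensatory change: both paired
    endpoints, but the purine moved from one strand to the other.
    Symmetric in its arguments.
    """
    if not (a.determinate and b.determinate):
        raise IndeterminateStateError(
            f"orientation_flip requires determinate states, got {a} and {b}"
        )
    return {a.orientation, b.orientation} == {Orientation.PUR_PYR, Orientation.PYR_PUR}


class EventKind(str, Enum):
    NO_CHANGE = "no_change"
    HCBC = "hcbc"
    FCBC = "fcbc"
    MISMATCH_GAIN = "mismatch_gain"
    MISMATCH_RESOLUTION = "mismatch_resolution"
    OTHER_DOUBLE = "other_double"


class FcbcType(str, Enum):
    I = "I"
    II = "II"
    ABSENT = "absent"


class Side(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class EventClass:
    """Classification of one pair-state transition.

    ``fcbc_type`` is I or II exactly when ``kind`` is FCBC; ``changed_side``
    records which pair member(s) differ between the two endpoint states.
    """

    kind: EventKind
    fcbc_type: FcbcType = FcbcType.ABSENT
    changed_side: Side = Side.NONE

    def __post_init__(self) -> None:
        if (self.kind is EventKind.FCBC) != (self.fcbc_type is not FcbcType.ABSENT):
            raise ValueError("fcbc_type must be set iff kind is fcbc")
        if self.kind is EventKind.FCBC and self.changed_side is not Side.BOTH:
            raise ValueError("fcbc implies both sides changed")


# --- stem layouts -----------------------------------------------------------

# Canonical pair-index ranges per stem.  The acceptor stem always has 7
# pairs; the DHU stem 3-4 (absent from trnS1); the anticodon stem 5, with an
# extra 5'-side pair (index 0) in mammalian trnS1/trnS2; the TPsiC stem 4-6.
_AC_RANGE = (1, 7)
_DH_RANGE = (1, 4)
_AN_RANGE = (1, 5)
_TP_RANGE = (1, 6)


@dataclass(frozen=True)
class StemLayout:
    """The pair-coordinate scheme of one tRNA.

    ``stems`` is an ordered tuple of ``(stem_name, pair_indices)`` with
    indices numbered 5'->3' along each stem (1-7ac, 1-4dh, 0-5an, 1-6tp).
    """

    trna_id: str
    stems: Tuple[Tuple[str, Tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        if self.trna_id not in TRNA_NAMES:
            raise ValueError(
                f"unknown tRNA {self.trna_id!r}; valid names: {', '.join(TRNA_NAMES)}"
            )
        seen = set()
        for stem, indices in self.stems:
            if stem not in STEM_NAMES:
                raise ValueError(f"unknown stem {stem!r}")
            if stem in seen:
                raise ValueError(f"duplicate stem {stem!r}")
            seen.add(stem)
            if list(indices) != sorted(indices) or len(set(indices)) != len(indices):
                raise ValueError(f"{stem} pair indices must be 5'->3' ordered")
            if indices and indices != tuple(range(indices[0], indices[-1] + 1)):
                raise ValueError(f"{stem} pair indices must be consecutive")
        by_stem = dict(self.stems)
        ac = by_stem.get("ac", ())
        if tuple(ac) != tuple(range(1, 8)):
            raise ValueError("acceptor stem must carry exactly pairs 1-7")
        if self.trna_id == "trnS1" and by_stem.get("dh"):
            raise ValueError("trnS1 has no DHU stem")
        an = by_stem.get("an", ())
        if an and an[0] == 0 and self.trna_id not in ("trnS1", "trnS2"):
            raise ValueError("anticodon pair 0 occurs only in trnS1/trnS2")
        for stem, rng in (("dh", _DH_RANGE), ("an", _AN_RANGE), ("tp", _TP_RANGE)):
            idx = by_stem.get(stem, ())
            lo = 0 if (stem == "an" and self.trna_id in ("trnS1", "trnS2")) else rng[0]
            for i in idx:
                if not (lo <= i <= rng[1]):
                    raise ValueError(f"{stem} pair index {i} outside {lo}-{rng[1]}")

    @property
    def pairs(self) -> Tuple[Tuple[str, int], ...]:
        """All (stem, pair_index) slots in layout order."""
        return tuple((s, i) for s, idx in self.stems for i in idx)

    def pair_label(self, stem: str, index: int) -> str:
        """Render a pair as in figures, e.g. ``"2tp"`` or ``"0an"``."""
        return f"{index}{stem}"


def canonical_stem_layout(trna_id: str) -> StemLayout:
    """Template layout for one of the 22 tRNAs.

    The acceptor stem is fixed at 7 pairs.  The DHU and TPsiC stems get
    their maximal canonical ranges (4 and 6 pairs); a stem-annotation table
    binds the actual per-alignment counts.  trnS1 has no DHU stem, and
    trnS1/trnS2 carry the extra anticodon pair numbered 0.
    """
    if trna_id not in TRNA_NAMES:
        raise ValueError(
            f"unknown tRNA {trna_id!r}; valid names: {', '.join(TRNA_NAMES)}"
        )
    stems = [("ac", tuple(range(1, 8)))]
    if trna_id != "trnS1":
        stems.append(("dh", tuple(range(1, 5))))
    an_start = 0 if trna_id in ("trnS1", "trnS2") else 1
    stems.append(("an", tuple(range(an_start, 6))))
    stems.append(("tp", tuple(range(1, 7))))
    return StemLayout(trna_id, tuple(stems))
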