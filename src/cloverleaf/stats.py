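"""Composition, skew, saturation and codon-usage statistics.

AT-skew = (A-T)/(A+T) and GC-skew = (G-C)/(G+C) measure strand compositional
asymmetry; applied either to the annotated stem positions of one tRNA or to
a whole mtDNA strand.  Zero-denominator skews are reported as missing (None)
rather than zero so that ranges across taxa are not artificially shrunk.

Saturation is diagnosed per orthologous alignment as the mean over all
unordered taxon pairs of (corrected distance - p-distance): near zero when
multiple hits are rare, growing as the observed p-distance undershoots the
true number of substitutions.  The corrected distance is the closed-form
pairwise Tamura-Nei (TN93) maximum-likelihood estimator — the substitution
model underlying composite-likelihood distances — computed from the pooled
base frequencies of each sequence pair.

Codon-family usage counts codons per thousand over the 22 mitochondrial tRNA
families under the vertebrate mitochondrial code, excluding stop codons
(not served by any tRNA) and the initiation codon of every CDS (always read
as formyl-Met whatever the codon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import CdsRecord, OrthologousStemSet

__all__ = [
    "StemProfile",
    "SaturationSummary",
    "stem_composition_profile",
    "profile_ranges",
    "pairwise_p_distance",
    "corrected_distance",
    "saturation_summary",
    "codon_family_usage",
    "strand_skews",
    "CODON_FAMILIES",
]

_BASES = "ACGT"


def _skew(x: int, y: int) -> Optional[float]:
    return (x - y) / (x + y) if x + y else None


@dataclass(frozen=True)
class StemProfile:
    """Base composition of one taxon's annotated stem positions."""

    taxon: str
    trna_id: str
    counts: Dict[str, int]
    at_percent: Optional[float]
    gc_percent: Optional[float]
    at_skew: Optional[float]
    gc_skew: Optional[float]

    @property
    def n_positions(self) -> int:
        return sum(self.counts.values())


def _profile_from_counts(taxon: str, trna_id: str, counts: Dict[str, int]) -> StemProfile:
    total = sum(counts.values())
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    return StemProfile(
        taxon=taxon,
        trna_id=trna_id,
        counts=dict(counts),
        at_percent=100.0 * at / total if total else None,
        gc_percent=100.0 * gc / total if total else None,
        at_skew=_skew(counts["A"], counts["T"]),
        gc_skew=_skew(counts["G"], counts["C"]),
    )


def stem_composition_profile(stem_set: OrthologousStemSet, taxon: str) -> StemProfile:
    """Count A/C/G/T over all determinate annotated stem positions (both
    members of every present pair) of one taxon and derive A+T%, G+C% and
    the two skews."""
    if taxon not in stem_set.pair_states:
        raise KeyError(f"unknown taxon {taxon!r} for {stem_set.trna_id}")
    counts = {b: 0 for b in _BASES}
    for state in stem_set.pair_states[taxon].values():
        if state is None:
            continue
        for base in (state.base5, state.base3):
            if base in counts:
                counts[base] += 1
    return _profile_from_counts(taxon, stem_set.trna_id, counts)


_RANGE_FIELDS = ("at_percent", "gc_percent", "at_skew", "gc_skew")


def profile_ranges(profiles: Sequence[StemProfile]) -> pd.DataFrame:
    """Per-tRNA min/max/range of composition and skews across taxa.

    Requires at least two taxa per tRNA.  Missing (undefined) skews are
    excluded; a quantity undefined for every taxon yields NaN with its
    ``*_all_undefined`` flag set.  Skew columns get a ``*_fluctuates`` flag
    marking sign changes (min < 0 < max) across taxa.
    """
    by_trna: Dict[str, List[StemProfile]] = {}
    for p in profiles:
        by_trna.setdefault(p.trna_id, []).append(p)
    rows = {}
    for trna, group in sorted(by_trna.items()):
        if len(group) < 2:
            raise ValueError(f"{trna}: ranges need at least 2 taxa, got {len(group)}")
        row: Dict[str, object] = {}
        for f in _RANGE_FIELDS:
            vals = [getattr(p, f) for p in group if getattr(p, f) is not None]
            if vals:
                lo, hi = min(vals), max(vals)
                row[f"{f}_min"], row[f"{f}_max"] = lo, hi
                row[f"{f}_range"] = hi - lo
                row[f"{f}_all_undefined"] = False
            else:
                row[f"{f}_min"] = row[f"{f}_max"] = row[f"{f}_range"] = math.nan
                row[f"{f}_all_undefined"] = True
            if f.endswith("_skew"):
                row[f"{f}_fluctuates"] = bool(vals) and min(vals) < 0 < max(vals)
        rows[trna] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "trna_id"
    return df


# --- distances --------------------------------------------------------------


def _comparable_sites(seq_a: str, seq_b: str) -> List[Tuple[str, str]]:
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    return [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]


def pairwise_p_distance(seq_a: str, seq_b: str) -> Optional[float]:
    """Proportion of differing sites among pairwise-comparable sites
    (columns where both sequences carry an unambiguous base).  ``None`` when
    no site is comparable."""
    sites = _comparable_sites(seq_a, seq_b)
    if not sites:
        return None
    return sum(1 for x, y in sites if x != y) / len(sites)


def corrected_distance(seq_a: str, seq_b: str) -> Optional[float]:
    """Closed-form pairwise Tamura-Nei (TN93) maximum-likelihood distance.

    Base frequencies are pooled over both sequences at comparable sites; the
    two transition classes (A<->G, C<->T) and the transversions enter
    separate log terms.  Returns ``None`` when the estimate is undefined —
    degenerate composition (a missing purine or pyrimidine class) or a
    non-positive log argument, the signature of full saturation.
    """
    sites = _comparable_sites(seq_a, seq_b)
    n = len(sites)
    if not n:
        return None
    freq = {b: 0 for b in _BASES}
    p1 = p2 = q = 0
    for x, y in sites:
        freq[x] += 1
        freq[y] += 1
        if x != y:
            duo = {x, y}
            if duo == {"A", "G"}:
                p1 += 1
            elif duo == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    pi = {b: freq[b] / (2 * n) for b in _BASES}
    piR = pi["A"] + pi["G"]
    piY = pi["C"] + pi["T"]
    P1, P2, Q = p1 / n, p2 / n, q / n

    if piR == 0 or piY == 0:
        # No purines (or pyrimidines) at all: TN93 degenerates.
        return 0.0 if P1 == P2 == Q == 0 else None

    k1 = 2 * pi["A"] * pi["G"] / piR
    k2 = 2 * pi["T"] * pi["C"] / piY
    k3 = 2 * (piR * piY - pi["A"] * pi["G"] * piY / piR - pi["T"] * pi["C"] * piR / piY)

    def _term(k: float, P: float, denom: float) -> Optional[float]:
        if k == 0:
            return None if P > 0 else 0.0
        w = 1 - P / k - Q / (2 * denom)
        return None if w <= 0 else -k * math.log(w)

    t1 = _term(k1, P1, piR)
    t2 = _term(k2, P2, piY)
    if t1 is None or t2 is None:
        return None
    w3 = 1 - Q / (2 * piR * piY)
    if w3 <= 0:
        return None
    return t1 + t2 - k3 * math.log(w3)


@dataclass
class SaturationSummary:
    """Per-pair distances and the saturation diagnostic for one alignment."""

    trna_id: str
    per_pair: pd.DataFrame  # columns: taxon_a, taxon_b, p_distance, corrected, difference
    mean_difference: Optional[float]
    sd_difference: Optional[float]
    n_pairs: int
    n_undefined: int = 0
    mean_p_distance: Optional[float] = None


def saturation_summary(
    sequences: Dict[str, str], trna_id: str = ""
) -> SaturationSummary:
    """Compute p-distance, TN93 corrected distance and their difference for
    every unordered taxon pair; the mean difference is the global saturation
    descriptor (standard deviation sample-based, n-1).

    Pairs with an undefined corrected distance are excluded from the mean
    and counted in ``n_undefined``.
    """
    if hasattr(sequences, "alignment"):  # accept an OrthologousStemSet
        trna_id = trna_id or sequences.trna_id
        sequences = sequences.alignment
    taxa = list(sequences)
    if len(taxa) < 2:
        raise ValueError("saturation summary needs at least 2 taxa")
    rows = []
    for a, b in combinations(taxa, 2):
        p = pairwise_p_distance(sequences[a], sequences[b])
        d = corrected_distance(sequences[a], sequences[b])
        diff = d - p if (p is not None and d is not None) else None
        rows.append((a, b, p, d, diff))
    df = pd.DataFrame(
        rows, columns=["taxon_a", "taxon_b", "p_distance", "corrected", "difference"]
    )
    diffs = df["difference"].dropna()
    ps = df["p_distance"].dropna()
    return SaturationSummary(
        trna_id=trna_id,
        per_pair=df,
        mean_difference=float(diffs.mean()) if len(diffs) else None,
        sd_difference=float(diffs.std(ddof=1)) if len(diffs) > 1 else None,
        n_pairs=len(df),
        n_undefined=int(df["difference"].isna().sum()),
        mean_p_distance=float(ps.mean()) if len(ps) else None,
    )


# --- codon families ---------------------------------------------------------

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
_STOPS = frozenset(_MITO_TABLE.stop_codons)  # TAA, TAG, AGA, AGG


def _codon_family(codon: str) -> str:
    aa = _MITO_TABLE.forward_table[codon]
    if aa == "L":
        return "trnL1" if codon.startswith("CT") else "trnL2"  # CTN vs TTR
    if aa == "S":
        return "trnS1" if codon.startswith("AG") else "trnS2"  # AGY vs TCN
    return f"trn{aa}"


#: Sense codons of the vertebrate mitochondrial code grouped by the tRNA
#: family that decodes them.
CODON_FAMILIES: Dict[str, Tuple[str, ...]] = {}
for _codon in sorted(_MITO_TABLE.forward_table):
    CODON_FAMILIES.setdefault(_codon_family(_codon), ())
    CODON_FAMILIES[_codon_family(_codon)] += (_codon,)


@dataclass
class CodonUsage:
    """Codon-family usage over a CDS collection."""

    counts: Dict[str, int]
    per_thousand: Dict[str, float]
    n_codons_retained: int
    n_excluded_stops: int
    n_excluded_starts: int


def codon_family_usage(cds_records: Sequence[CdsRecord]) -> CodonUsage:
    """Count codons per thousand for the 22 tRNA codon families.

    The first codon of every CDS is excluded (initiation is formyl-Met
    regardless of codon), stop codons are excluded (no tRNA family), and
    codons containing ambiguity codes are ignored.
    """
    if not cds_records:
        raise ValueError("codon_family_usage: empty CDS input")
    counts = {f"trn{x}": 0 for x in "ACDEFGHIKMNPQRTVWY"}
    counts.update({"trnL1": 0, "trnL2": 0, "trnS1": 0, "trnS2": 0})
    n_stops = n_starts = 0
    for rec in cds_records:
        seq = rec.sequence.upper().replace("U", "T")
        codons = [seq[i: i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        if not codons:
            continue
        codons = codons[1:]  # initiation codon
        n_starts += 1
        for codon in codons:
            if codon in _STOPS:
                n_stops += 1
            elif codon in _MITO_TABLE.forward_table:
                counts[_codon_family(codon)] += 1
    retained = sum(counts.values())
    per_thousand = {
        fam: (1000.0 * c / retained if retained else 0.0)
        for fam, c in sorted(counts.items())
    }
    return CodonUsage(
        counts=counts,
        per_thousand=per_thousand,
        n_codons_retained=retained,
        n_excluded_stops=n_stops,
        n_excluded_starts=n_starts,
    )


# --- whole-strand skews -----------------------------------------------------


def strand_skews(genome_sequence: str) -> Dict[str, Optional[float]]:
    """AT/GC skew and A+T% / G+C% of one strand of a (circular) genome.

    Apply to the alpha strand for the conventional whole-mtDNA statistics;
    complementing the strand negates both skews exactly.
    """
    seq = genome_sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty genome sequence")
    counts = {b: seq.count(b) for b in _BASES}
    total = sum(counts.values())
    return {
        "at_skew": _skew(counts["A"], counts["T"]),
        "gc_skew": _skew(counts["G"], counts["C"]),
        "at_percent": 100.0 * (counts["A"] + counts["T"]) / total if total else None,
        "gc_percent": 100.0 * (counts["G"] + counts["C"]) / total if total else None,
        "length": len(seq),
    }
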