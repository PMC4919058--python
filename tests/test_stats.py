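"""Composition, skew, distance and codon-usage statistics against hand
counts and closed-form oracles."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_stem_set

from cloverleaf.io import CdsRecord
from cloverleaf.stats import (
    CODON_FAMILIES,
    codon_family_usage,
    corrected_distance,
    pairwise_p_distance,
    profile_ranges,
    saturation_summary,
    stem_composition_profile,
    strand_skews,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _stem_set_from_duos(duos_by_taxon):
    return build_stem_set("trnA", duos_by_taxon)


class TestStemProfile:
    def test_balanced_stem_has_zero_skew(self):
        ss = _stem_set_from_duos({"x": [("A", "T")] * 7})
        p = stem_composition_profile(ss, "x")
        assert p.at_skew == 0.0
        assert p.at_percent == 100.0
        assert p.n_positions == 14

    def test_skew_formula_direct(self):
        # stem bases AAAT across two pairs -> AT-skew (3-1)/(3+1)
        ss = _stem_set_from_duos(
            {"x": [("A", "A"), ("A", "T")] + [("G", "C")] * 5}
        )
        p = stem_composition_profile(ss, "x")
        assert p.at_skew == pytest.approx((3 - 1) / (3 + 1))

    def test_zero_denominator_skew_is_undefined_not_zero(self):
        ss = _stem_set_from_duos({"x": [("G", "C")] * 7})
        p = stem_composition_profile(ss, "x")
        assert p.at_skew is None
        assert p.gc_percent == 100.0

    def test_absent_pairs_excluded_from_counts(self):
        ss = _stem_set_from_duos({"x": [("A", "T")] * 6 + [("-", "-")]})
        assert stem_composition_profile(ss, "x").n_positions == 12

    def test_unknown_taxon(self):
        ss = _stem_set_from_duos({"x": [("A", "T")] * 7})
        with pytest.raises(KeyError):
            stem_composition_profile(ss, "y")


class TestProfileRanges:
    def _profiles(self, duos_list):
        ss = _stem_set_from_duos(
            {f"t{i}": duos for i, duos in enumerate(duos_list)}
        )
        return [stem_composition_profile(ss, t) for t in ss.taxa]

    def test_range_and_sign_fluctuation(self):
        # at_skew +1/3 vs -1/3 across taxa: range 2/3, sign fluctuates
        profiles = self._profiles(
            [
                [("A", "A"), ("A", "T"), ("T", "A")] + [("G", "C")] * 4,  # A:4 T:2
                [("T", "T"), ("A", "T"), ("T", "A")] + [("G", "C")] * 4,  # A:2 T:4
            ]
        )
        df = profile_ranges(profiles)
        row = df.loc["trnA"]
        assert row["at_skew_range"] == pytest.approx(2 / 3)
        assert bool(row["at_skew_fluctuates"]) is True

    def test_identical_profiles_zero_range(self):
        profiles = self._profiles([[("A", "T")] * 7] * 2)
        row = profile_ranges(profiles).loc["trnA"]
        assert row["at_percent_range"] == 0.0
        assert bool(row["at_skew_fluctuates"]) is False

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError, match="2 taxa"):
            profile_ranges(self._profiles([[("A", "T")] * 7]))

    def test_all_undefined_skew_flagged(self):
        profiles = self._profiles([[("G", "C")] * 7] * 2)
        row = profile_ranges(profiles).loc["trnA"]
        assert bool(row["at_skew_all_undefined"]) is True
        assert math.isnan(row["at_skew_range"])


class TestPDistance:
    def test_identical_and_single_difference(self):
        assert pairwise_p_distance("ACGT", "ACGT") == 0.0
        assert pairwise_p_distance("ACGT", "ACGA") == 0.25

    def test_gapped_and_ambiguous_columns_excluded_pairwise(self):
        assert pairwise_p_distance("AC-T", "ACNT") == 0.0
        assert pairwise_p_distance("----", "ACGT") is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_direct_recount(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 60)
        a = "".join(rng.choice("ACGT-N") for _ in range(n))
        b = "".join(rng.choice("ACGT-N") for _ in range(n))
        sites = [
            (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
        ]
        expected = (
            None if not sites else sum(x != y for x, y in sites) / len(sites)
        )
        assert pairwise_p_distance(a, b) == expected


def _mutate_jc(seq, d, rng):
    """Evolve a sequence for distance d under equal rates (Jukes-Cantor):
    per-site difference probability p = 3/4 (1 - exp(-4d/3))."""
    p = 0.75 * (1 - math.exp(-4 * d / 3))
    out = []
    for b in seq:
        if rng.random() < p:
            out.append(rng.choice([x for x in "ACGT" if x != b]))
        else:
            out.append(b)
    return "".join(out)


class TestCorrectedDistance:
    def test_identical_sequences(self):
        assert corrected_distance("ACGTACGT", "ACGTACGT") == pytest.approx(0.0)

    def test_always_at_least_p_distance(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(20, 80)
            a = "".join(rng.choice("ACGT") for _ in range(n))
            b = _mutate_jc(a, rng.uniform(0, 0.5), rng)
            p = pairwise_p_distance(a, b)
            d = corrected_distance(a, b)
            if d is not None:
                assert d >= p - 1e-12

    def test_jc_limit_at_large_n(self):
        """Equal-rate simulation at true distance 0.1, 10k sites: the TN93
        closed form must agree with the Jukes-Cantor closed form within
        sampling error."""
        rng = random.Random(1)
        a = "".join(rng.choice("ACGT") for _ in range(10_000))
        b = _mutate_jc(a, 0.1, rng)
        p = pairwise_p_distance(a, b)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        tn93 = corrected_distance(a, b)
        assert tn93 == pytest.approx(jc, abs=0.005)
        assert tn93 == pytest.approx(0.1, abs=0.015)

    def test_matches_independent_tn93_oracle(self):
        """Frozen cross-check against R ape::dist.dna(model="TN93") on a
        deterministic 600-site pair with transition-biased differences."""
        rng = random.Random(2024)
        a = "".join(rng.choice("ACGT") for _ in range(600))
        transit = {"A": "G", "G": "A", "C": "T", "T": "C"}
        b = []
        for ch in a:
            r = rng.random()
            if r < 0.08:
                b.append(transit[ch])
            elif r < 0.11:
                b.append(rng.choice([x for x in "ACGT" if x != ch]))
            else:
                b.append(ch)
        d = corrected_distance(a, "".join(b))
        assert d == pytest.approx(0.1575643995, abs=1e-9)

    def test_saturated_pair_reported_undefined(self):
        # maximally divergent two-state composition drives the log negative
        assert corrected_distance("A" * 50, "G" * 50) is None


class TestSaturationSummary:
    def test_identical_alignment_zero_difference(self):
        seqs = {t: "ACGTACGTAC" for t in "abcd"}
        sat = saturation_summary(seqs, "trnA")
        assert sat.mean_difference == pytest.approx(0.0)
        assert sat.n_pairs == 6

    def test_two_taxon_mean_is_single_pair(self):
        seqs = {"a": "ACGTACGTACGTACGT", "b": "ACGTACGTACGTACGA"}
        sat = saturation_summary(seqs)
        diff = corrected_distance(seqs["a"], seqs["b"]) - pairwise_p_distance(
            seqs["a"], seqs["b"]
        )
        assert sat.mean_difference == pytest.approx(diff)
        assert sat.sd_difference is None

    def test_five_taxon_mean_equals_hand_average(self):
        rng = random.Random(5)
        seqs = {}
        base = "".join(rng.choice("ACGT") for _ in range(40))
        for t in "abcde":
            seqs[t] = _mutate_jc(base, rng.uniform(0.05, 0.3), rng)
        sat = saturation_summary(seqs)
        diffs = []
        taxa = list(seqs)
        for i in range(5):
            for j in range(i + 1, 5):
                d = corrected_distance(seqs[taxa[i]], seqs[taxa[j]])
                p = pairwise_p_distance(seqs[taxa[i]], seqs[taxa[j]])
                if d is not None:
                    diffs.append(d - p)
        assert sat.n_pairs == 10
        assert sat.mean_difference == pytest.approx(sum(diffs) / len(diffs))

    def test_difference_shrinks_with_divergence(self):
        """Mean (corrected - p) falls monotonically as divergence drops."""
        rng = random.Random(11)
        base = "".join(rng.choice("ACGT") for _ in range(2000))
        means = []
        for d in (0.4, 0.2, 0.1, 0.02):
            seqs = {"r": base}
            for t in "ab":
                seqs[t] = _mutate_jc(base, d, rng)
            means.append(saturation_summary(seqs).mean_difference)
        assert means == sorted(means, reverse=True)
        assert means[-1] < 0.005


class TestCodonFamilyUsage:
    def test_families_partition_sense_codons(self):
        all_codons = [c for fam in CODON_FAMILIES.values() for c in fam]
        assert len(all_codons) == len(set(all_codons)) == 60  # 64 - 4 stops
        assert len(CODON_FAMILIES) == 22
        assert set(CODON_FAMILIES["trnL1"]) == {"CTA", "CTC", "CTG", "CTT"}
        assert set(CODON_FAMILIES["trnL2"]) == {"TTA", "TTG"}
        assert set(CODON_FAMILIES["trnS1"]) == {"AGC", "AGT"}

    def test_hand_counted_toy_cds(self):
        # ATG CTA CTG TAA: start and stop removed, both retained codons CTN
        usage = codon_family_usage([CdsRecord("toy", "ATGCTACTGTAA")])
        assert usage.n_codons_retained == 2
        assert usage.per_thousand["trnL1"] == pytest.approx(1000.0)

    def test_agy_serine_and_vertebrate_stops(self):
        # AGA is a stop in the vertebrate mitochondrial code; AGC is trnS1
        usage = codon_family_usage([CdsRecord("toy", "ATGAGCAGA")])
        assert usage.n_codons_retained == 1
        assert usage.per_thousand["trnS1"] == pytest.approx(1000.0)
        assert usage.n_excluded_stops == 1

    def test_per_thousand_sums_to_1000(self):
        rng = random.Random(3)
        seq = "ATG" + "".join(
            rng.choice([c for f in CODON_FAMILIES.values() for c in f])
            for _ in range(500)
        )
        usage = codon_family_usage([CdsRecord("toy", seq)])
        assert sum(usage.per_thousand.values()) == pytest.approx(1000.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            codon_family_usage([])


class TestStrandSkews:
    def test_balanced_toy_genome(self):
        s = strand_skews("AATT")
        assert s["at_skew"] == 0.0
        assert s["at_percent"] == 100.0

    def test_direct_count_oracle(self):
        seq = "AAAGGCT"
        s = strand_skews(seq)
        assert s["at_skew"] == pytest.approx((3 - 1) / 4)
        assert s["gc_skew"] == pytest.approx((2 - 1) / 3)
        assert s["length"] == 7

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=200))
    def test_complement_negates_both_skews(self, seq):
        fwd = strand_skews(seq)
        rev = strand_skews(seq.translate(COMPLEMENT))
        for key in ("at_skew", "gc_skew"):
            if fwd[key] is None:
                assert rev[key] is None
            else:
                assert rev[key] == pytest.approx(-fwd[key])
                assert -1.0 <= fwd[key] <= 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            strand_skews("")
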