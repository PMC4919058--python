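"""Ancestral reconstruction and event extraction against independent oracles."""

import random

import pytest

from conftest import brute_force_parsimony, build_stem_set

from cloverleaf.io import read_tree
from cloverleaf.mapping import (
    build_spic_catalog,
    extract_branch_events,
    fitch_reconstruct,
    map_events,
    reconstruct_pair_states,
    resolve_node_states,
    summarize_events,
)
from cloverleaf.model import EventKind, FcbcType, make_pair_state
from cloverleaf.classify import classify_transition


def random_topology(rng, tips):
    """Uniformly random rooted binary topology by sequential attachment."""
    newick = {t: t for t in tips}
    nodes = list(tips)
    while len(nodes) > 1:
        a, b = rng.sample(nodes, 2)
        nodes.remove(a)
        nodes.remove(b)
        merged = f"({newick[a]},{newick[b]})"
        key = a + b
        newick[key] = merged
        nodes.append(key)
    return newick[nodes[0]] + ";"


class TestFitch:
    def test_constant_column_needs_no_changes(self, quartet_tree):
        sets, length = fitch_reconstruct(
            quartet_tree, {t: "A" for t in "ABCD"}
        )
        assert length == 0
        assert all(s == frozenset("A") for s in sets.values())

    def test_two_state_quartet(self, quartet_tree):
        """((A:T,B:T),(C:G,D:G)): one change, root ambiguous {T,G} —
        matches the exhaustive-enumeration minimum."""
        tips = {"A": "T", "B": "T", "C": "G", "D": "G"}
        sets, length = fitch_reconstruct(quartet_tree, tips)
        assert length == 1
        assert sets[quartet_tree.root_id] == frozenset("TG")
        assert brute_force_parsimony(quartet_tree, tips) == 1

    def test_ambiguity_code_tip_is_uninformative(self, quartet_tree):
        tips = {"A": "T", "B": "N", "C": "T", "D": "T"}
        _, length = fitch_reconstruct(quartet_tree, tips)
        assert length == 0

    def test_missing_tip_state_rejected(self, quartet_tree):
        with pytest.raises(ValueError, match="D"):
            fitch_reconstruct(quartet_tree, {"A": "T", "B": "T", "C": "G"})

    def test_length_matches_brute_force_on_random_trees(self):
        """Seeded random topologies (4-6 tips, binary and multifurcating)
        against the exhaustive oracle."""
        rng = random.Random(7)
        for _ in range(40):
            n = rng.randint(4, 6)
            tips = [f"t{i}" for i in range(n)]
            phylo = read_tree(random_topology(rng, tips))
            states = {t: rng.choice("ACGT") for t in tips}
            _, length = fitch_reconstruct(phylo, states)
            assert length == brute_force_parsimony(phylo, states)
        # multifurcating: star and partially resolved
        for newick in ("(t0,t1,t2,t3,t4);", "((t0,t1,t2),(t3,t4));"):
            phylo = read_tree(newick)
            for _ in range(20):
                states = {t: rng.choice("ACGT") for t in phylo.tip_labels}
                _, length = fitch_reconstruct(phylo, states)
                assert length == brute_force_parsimony(phylo, states)

    def test_duplicating_a_tip_never_increases_length(self):
        rng = random.Random(13)
        for _ in range(20):
            tips = [f"t{i}" for i in range(5)]
            base = random_topology(rng, tips)
            states = {t: rng.choice("ACGT") for t in tips}
            _, len_base = fitch_reconstruct(read_tree(base), states)
            # attach an identical sister to t0
            dup = base.replace("t0", "(t0,t0dup)")
            states_dup = dict(states, t0dup=states["t0"])
            _, len_dup = fitch_reconstruct(read_tree(dup), states_dup)
            assert len_dup <= len_base


class TestResolve:
    def test_root_takes_lexicographic_minimum(self, quartet_tree):
        sets, _ = fitch_reconstruct(
            quartet_tree, {"A": "T", "B": "T", "C": "G", "D": "G"}
        )
        resolved, ties = resolve_node_states(sets, quartet_tree)
        assert resolved[quartet_tree.root_id] == "G"  # G < T
        assert ties >= 1

    def test_child_prefers_parent_state(self):
        phylo = read_tree("((A,B),(C,D));")
        sets, _ = fitch_reconstruct(phylo, {"A": "A", "B": "G", "C": "G", "D": "G"})
        resolved, _ = resolve_node_states(sets, phylo)
        # the (A,B) ancestor has candidates {A,G}; the root is G, so it
        # inherits G rather than taking its own lexicographic minimum
        ab_parent = phylo.parent("A")
        assert resolved[phylo.root_id] == "G"
        assert resolved[ab_parent] == "G"

    def test_singleton_sets_resolve_to_themselves(self, quartet_tree):
        sets, _ = fitch_reconstruct(quartet_tree, {t: "C" for t in "ABCD"})
        resolved, ties = resolve_node_states(sets, quartet_tree)
        assert set(resolved.values()) == {"C"}
        assert ties == 0


def _stem_set_for(tree_taxa, pair_bases):
    return build_stem_set("trnA", dict(zip(tree_taxa, pair_bases)))


class TestExtractEvents:
    def test_single_terminal_hcbc(self):
        phylo = read_tree("((a,b),(c,d));")
        wc = [("A", "T")] * 7
        hb = [("A", "T")] * 6 + [("G", "T")]
        ss = _stem_set_for("abcd", [wc, hb, wc, wc])
        events = map_events(ss, phylo)
        assert len(events) == 1
        ev = events[0]
        assert ev.event_class.kind is EventKind.HCBC
        assert ev.child_id == "b"
        assert ev.is_terminal
        assert str(ev.from_state) == "A-T" and str(ev.to_state) == "G.T"

    def test_no_variation_no_events(self):
        phylo = read_tree("((a,b),(c,d));")
        wc = [("A", "T")] * 7
        ss = _stem_set_for("abcd", [wc] * 4)
        assert map_events(ss, phylo) == []

    def test_stepwise_fcbc_path_yields_two_hcbcs(self):
        """A-T -> G.T -> G-C on a ladder: two hemi-compensatory steps whose
        endpoints compose to a type I fully compensatory pair."""
        phylo = read_tree("(((a,b),c),d);")
        at = [("A", "T")] * 7
        gt = [("A", "T")] * 6 + [("G", "T")]
        gc = [("A", "T")] * 6 + [("G", "C")]
        ss = _stem_set_for("abcd", [gc, gc, gt, at])
        events = map_events(ss, phylo)
        kinds = sorted(ev.event_class.kind.value for ev in events)
        assert kinds == ["hcbc", "hcbc"]
        composed = classify_transition(
            make_pair_state("A", "T"), make_pair_state("G", "C")
        )
        assert composed.kind is EventKind.FCBC
        assert composed.fcbc_type is FcbcType.I

    def test_indeterminate_tip_pair_skipped(self):
        phylo = read_tree("((a,b),(c,d));")
        wc = [("A", "T")] * 7
        amb = [("A", "T")] * 6 + [("N", "T")]
        ss = _stem_set_for("abcd", [wc, amb, wc, wc])
        annotated = reconstruct_pair_states(ss, phylo)
        assert extract_branch_events(annotated) == []
        assert annotated.skipped_pairs == 1

    def test_taxon_missing_from_tree_aborts_with_name(self):
        phylo = read_tree("((a,b),(c,d));")
        ss = _stem_set_for("abce", [[("A", "T")] * 7] * 4)
        with pytest.raises(ValueError, match="e"):
            map_events(ss, phylo)

    def test_ingroup_excludes_outgroup_branches(self):
        # derived change on the outgroup must not be tallied for the ingroup
        phylo = read_tree("(((a,b),c),out);")
        wc = [("A", "T")] * 7
        og = [("A", "T")] * 6 + [("G", "T")]
        ss = _stem_set_for(["a", "b", "c", "out"], [wc, wc, wc, og])
        all_events = map_events(ss, phylo)
        in_events = map_events(ss, phylo, ingroup=["a", "b", "c"])
        assert len(all_events) == 1 and all_events[0].child_id == "out"
        assert in_events == []


class TestSummaries:
    def _toy_events(self):
        phylo = read_tree("((a,b),(c,d));")
        at = [("A", "T")] * 7
        # b: FCBC-I at pair 1; c: HCBC at pair 2; d: mismatch at pair 3
        b = [("G", "C")] + [("A", "T")] * 6
        c = [("A", "T"), ("G", "T")] + [("A", "T")] * 5
        d = [("A", "T")] * 2 + [("A", "A")] + [("A", "T")] * 4
        ss = _stem_set_for("abcd", [at, b, c, d])
        return map_events(ss, phylo)

    def test_global_tallies_and_conservation(self):
        events = self._toy_events()
        summary = summarize_events(events)
        assert summary.total == 3
        assert (summary.fcbc, summary.hcbc, summary.mismatch) == (1, 1, 1)
        assert summary.fcbc_type_i == 1 and summary.fcbc_type_ii == 0
        per_trna_total = sum(
            sum(v.values()) for v in summary.per_trna.values()
        )
        assert per_trna_total == summary.total
        assert summary.terminal["all"] + summary.internal["all"] == summary.total

    def test_terminal_percentages(self):
        summary = summarize_events(self._toy_events())
        # every toy event sits on a terminal branch
        assert summary.terminal_percent["all"] == 100.0

    def test_empty_event_list_gives_zero_report(self):
        summary = summarize_events([])
        assert summary.total == 0
        assert summary.terminal_percent["all"] is None

    def test_strand_attribution(self):
        summary = summarize_events(self._toy_events())
        # trnA is beta-strand encoded
        assert sum(summary.per_strand["beta"].values()) == 3
        assert sum(summary.per_strand["alpha"].values()) == 0


class TestSpicCatalog:
    def test_grouping_by_pair_and_side(self):
        phylo = read_tree("((a,b),(c,d));")
        at = [("A", "T")] * 7
        # two independent 5' HCBCs at the same pair (b and c), one FCBC at pair 2 (d)
        b = [("G", "T")] + [("A", "T")] * 6
        c = [("G", "T")] + [("A", "T")] * 6
        d = [("A", "T"), ("G", "C")] + [("A", "T")] * 5
        ss = _stem_set_for("abcd", [at, b, c, d])
        events = map_events(ss, phylo)
        spics = build_spic_catalog(events)
        assert len(spics) == 2
        by_key = {(s.pair_index, s.side): s for s in spics}
        hcbc_spic = by_key[(1, "five_prime")]
        assert hcbc_spic.event_counts["hcbc"] == 2
        fcbc_spic = by_key[(2, "pair_level")]
        assert fcbc_spic.classes_observed == ("fcbc",)
        assert fcbc_spic.percent_of_spics == 50.0

    def test_empty_catalog(self):
        assert build_spic_catalog([]) == []
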