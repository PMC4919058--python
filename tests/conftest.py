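"""Shared fixtures: tiny hand-built stem sets, trees and file writers."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import pytest

from cloverleaf.io import OrthologousStemSet, PairSlot, Phylogeny, read_tree
from cloverleaf.model import StemLayout, make_pair_state


def build_stem_set(
    trna_id: str,
    pair_bases: Dict[str, List[Tuple[str, str]]],
    stems: Tuple[Tuple[str, Tuple[int, ...]], ...] = (("ac", (1, 2, 3, 4, 5, 6, 7)),),
) -> OrthologousStemSet:
    """Construct an OrthologousStemSet from explicit per-taxon pair bases.

    ``pair_bases[taxon]`` lists (base5, base3) duos in layout-pair order;
    use ('-', '-') for a pair absent from that taxon.  Columns are laid out
    pairwise: pair k occupies columns 2k+1 (5') and 2k+2 (3').
    """
    layout = StemLayout(trna_id, stems)
    pairs = layout.pairs
    slots = tuple(
        PairSlot(stem, idx, 2 * k + 1, 2 * k + 2)
        for k, (stem, idx) in enumerate(pairs)
    )
    taxa = tuple(pair_bases)
    alignment = {
        t: "".join(itertools.chain.from_iterable(pair_bases[t])) for t in taxa
    }
    pair_states = {}
    for t in taxa:
        states = {}
        for k, key in enumerate(pairs):
            b5, b3 = pair_bases[t][k]
            states[key] = None if b5 in "-." and b3 in "-." else make_pair_state(b5, b3)
        pair_states[t] = states
    return OrthologousStemSet(
        trna_id=trna_id,
        taxa=taxa,
        alignment=alignment,
        layout=layout,
        slots=slots,
        pair_states=pair_states,
    )


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return read_tree("((A:1,B:1):1,(C:1,D:1):1);")


def brute_force_parsimony(
    phylo: Phylogeny, tip_states: Dict[str, str]
) -> int:
    """Independent parsimony oracle: minimum edge-change count over all
    internal-node labelings, by exhaustive enumeration."""
    internals = [n for n in phylo.postorder_ids() if not phylo.is_tip(n)]
    best = None
    for labels in itertools.product("ACGT", repeat=len(internals)):
        assign = dict(zip(internals, labels))
        assign.update(tip_states)
        cost = sum(
            assign[p] != assign[c] for p, c in phylo.branches()
        )
        best = cost if best is None else min(best, cost)
    return best
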