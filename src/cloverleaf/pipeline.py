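"""End-to-end orchestration: inputs in, report bundle out.

``run_pipeline`` loads per-tRNA stem alignments, the reference tree and
(optionally) annotated genomes, then emits the full report bundle: the
branch-event table, per-node summaries, the SPIC catalogue, per-tRNA
composition ranges, saturation summaries, codon usage, and a JSON digest of
all global tallies.  Everything is deterministic given fixed inputs; a rerun
produces a byte-identical digest.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import io as cio
from .mapping import (
    build_spic_catalog,
    extract_branch_events,
    reconstruct_pair_states,
    summarize_events,
)
from .stats import (
    codon_family_usage,
    profile_ranges,
    saturation_summary,
    stem_composition_profile,
)

__all__ = ["run_pipeline", "load_stem_sets"]

logger = logging.getLogger(__name__)

DIGEST_SCHEMA_VERSION = 1


def load_stem_sets(
    alignments_dir: Union[str, Path], annotation_path: Union[str, Path]
) -> List[cio.OrthologousStemSet]:
    """Load every ``<trna_id>.fasta`` in a directory against one shared
    stem-annotation table."""
    alignments_dir = Path(alignments_dir)
    paths = sorted(alignments_dir.glob("*.fasta")) + sorted(
        alignments_dir.glob("*.fa")
    )
    if not paths:
        raise ValueError(f"no FASTA alignments found in {alignments_dir}")
    return [cio.read_stem_alignment(p, annotation_path) for p in paths]


def _collapse_taxa(
    stem_sets: Sequence[cio.OrthologousStemSet],
    phylo: cio.Phylogeny,
    collapse: Dict[str, Sequence[str]],
) -> cio.Phylogeny:
    """Collapse groups of tips (e.g. conspecific representatives) to a single
    tip: the group's first member is kept and renamed, the rest pruned from
    tree and alignments."""
    tree = phylo.tree
    for new_name, members in collapse.items():
        members = list(members)
        keep, drop = members[0], members[1:]
        taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in drop]
        if taxa:
            tree.prune_taxa(taxa)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == keep:
                leaf.taxon.label = new_name
        for ss in stem_sets:
            for name in drop:
                ss.alignment.pop(name, None)
                ss.pair_states.pop(name, None)
            if keep in ss.alignment:
                ss.alignment[new_name] = ss.alignment.pop(keep)
                ss.pair_states[new_name] = ss.pair_states.pop(keep)
            ss.taxa = tuple(t for t in ss.alignment)
    return cio.Phylogeny(tree)


def run_pipeline(
    alignments_dir: Union[str, Path],
    annotation_path: Union[str, Path],
    tree_path: Union[str, Path],
    out_dir: Union[str, Path],
    genomes: Optional[Union[str, Path]] = None,
    boundary_filter: bool = True,
    ingroup: Optional[Sequence[str]] = None,
    outgroup: Optional[Sequence[str]] = None,
    collapse: Optional[Dict[str, Sequence[str]]] = None,
) -> dict:
    """Run the whole analysis and write the report bundle to ``out_dir``.

    Outputs: ``events.tsv``, ``node_summary.json``, ``spic_catalog.tsv``,
    ``profile_ranges.tsv``, ``saturation.tsv``, ``codon_usage.tsv`` (when
    genomes are given), and ``digest.json``.  Returns the digest dict.

    Raises on any validation failure (taxa missing from the tree, illegal
    layouts, unreadable inputs); partial outputs are removed first.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stem_sets = load_stem_sets(alignments_dir, annotation_path)
    phylo = cio.read_tree(tree_path, outgroup=outgroup)
    if collapse:
        phylo = _collapse_taxa(stem_sets, phylo, collapse)
    for ss in stem_sets:
        cio.check_taxa_against_tree(ss.taxa, phylo)

    # --- event mapping
    all_events = []
    node_counts: Dict[str, Counter] = {}
    ties = 0
    skipped = 0
    for ss in stem_sets:
        annotated = reconstruct_pair_states(ss, phylo)
        ties += annotated.ties
        skipped += annotated.skipped_pairs
        all_events.extend(
            extract_branch_events(
                annotated, boundary_filter=boundary_filter, ingroup=ingroup
            )
        )
    summary = summarize_events(all_events)
    spics = build_spic_catalog(all_events)

    cio.write_event_table(all_events, out_dir / "events.tsv")

    for ev in all_events:
        node_counts.setdefault(ev.child_id, Counter())[
            "fcbc" if ev.event_class.kind.value == "fcbc"
            else "hcbc" if ev.event_class.kind.value == "hcbc"
            else "mismatch" if ev.event_class.kind.value.startswith("mismatch")
            else "other_double"
        ] += 1
    node_summary = {
        nid: {**dict(c), "csbps": sum(v for k, v in c.items() if k != "other_double")}
        for nid, c in sorted(node_counts.items())
    }
    (out_dir / "node_summary.json").write_text(
        json.dumps(node_summary, indent=1, sort_keys=True) + "\n"
    )

    pd.DataFrame(
        [
            {
                "trna_id": s.trna_id,
                "pair": f"{s.pair_index}{s.stem}",
                "side": s.side,
                **{f"n_{c}": n for c, n in s.event_counts.items()},
                "percent_of_spics": s.percent_of_spics,
                "percent_of_csbps": s.percent_of_csbps,
            }
            for s in spics
        ]
    ).to_csv(out_dir / "spic_catalog.tsv", sep="\t", index=False)

    # --- composition and saturation
    profiles = [
        stem_composition_profile(ss, taxon)
        for ss in stem_sets
        for taxon in ss.taxa
    ]
    ranges = profile_ranges(profiles)
    ranges.to_csv(out_dir / "profile_ranges.tsv", sep="\t")

    sat_rows = []
    for ss in stem_sets:
        sat = saturation_summary(ss.alignment, trna_id=ss.trna_id)
        sat_rows.append(
            {
                "trna_id": ss.trna_id,
                "mean_p_distance": sat.mean_p_distance,
                "mean_difference": sat.mean_difference,
                "sd_difference": sat.sd_difference,
                "n_pairs": sat.n_pairs,
                "n_undefined": sat.n_undefined,
            }
        )
    sat_df = pd.DataFrame(sat_rows)
    sat_df.to_csv(out_dir / "saturation.tsv", sep="\t", index=False)

    # --- codon usage and whole-genome skews (optional)
    codon_block = None
    if genomes is not None:
        cds = cio.read_cds_records(genomes)
        usage = codon_family_usage(cds)
        pd.DataFrame(
            sorted(usage.per_thousand.items()), columns=["family", "per_thousand"]
        ).to_csv(out_dir / "codon_usage.tsv", sep="\t", index=False)
        codon_block = {
            "n_codons_retained": usage.n_codons_retained,
            "n_excluded_stops": usage.n_excluded_stops,
            "n_excluded_starts": usage.n_excluded_starts,
            "per_thousand": usage.per_thousand,
        }

    digest = {
        "schema_version": DIGEST_SCHEMA_VERSION,
        "n_trnas": len(stem_sets),
        "n_taxa": len(phylo.tip_labels),
        "boundary_filter": boundary_filter,
        "events": summary.as_dict(),
        "n_spics": len(spics),
        "reconstruction_ties": ties,
        "skipped_indeterminate_pairs": skipped,
        "saturation_mean_difference": {
            r["trna_id"]: r["mean_difference"] for r in sat_rows
        },
        "codon_usage": codon_block,
    }
    # internal consistency: class totals add up, terminal+internal = total
    ev = digest["events"]
    assert ev["total_csbps"] == ev["fcbc"] + ev["hcbc"] + ev["mismatch"]
    assert ev["terminal"]["all"] + ev["internal"]["all"] == ev["total_csbps"]
    (out_dir / "digest.json").write_text(
        json.dumps(digest, indent=1, sort_keys=True) + "\n"
    )
    return digest
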