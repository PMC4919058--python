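"""Readers and writers: stem-annotated alignments, trees, CDS sets, event tables.

Formats are the field's plain-text standards: FASTA for alignments, a small
TSV for stem-pair annotations (1-based inclusive alignment columns, the way
alignment figures are read), Newick for the reference tree, GenBank flatfile
or FASTA for coding sequences, and TSV for event tables.  Parsing is
delegated to Biopython and dendropy; this module adds the validation and the
in-memory containers the analysis operates on.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
from Bio import SeqIO

from .model import (
    EventClass,
    EventKind,
    FcbcType,
    PairState,
    Side,
    StemLayout,
    make_pair_state,
)

__all__ = [
    "PairSlot",
    "OrthologousStemSet",
    "Phylogeny",
    "CdsRecord",
    "read_stem_alignment",
    "read_stem_annotation",
    "read_tree",
    "read_cds_records",
    "write_event_table",
    "read_event_table",
    "write_stem_alignment",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PairSlot:
    """One annotated stem pair bound to concrete alignment columns
    (1-based, inclusive)."""

    stem: str
    pair_index: int
    col5: int
    col3: int


@dataclass
class OrthologousStemSet:
    """One tRNA's orthologous alignment with its stem pairs materialised.

    ``pair_states[taxon][(stem, pair_index)]`` is a
    :class:`~cloverleaf.model.PairState`, or ``None`` when both annotated
    columns are gaps for that taxon (the pair is absent from that taxon's
    stem, not a mismatch).  ``lengths_vary[stem]`` is True when the number
    of present pairs in that stem differs across taxa.
    """

    trna_id: str
    taxa: Tuple[str, ...]
    alignment: Dict[str, str]
    layout: StemLayout
    slots: Tuple[PairSlot, ...]
    pair_states: Dict[str, Dict[Tuple[str, int], Optional[PairState]]] = field(
        default_factory=dict
    )

    @property
    def lengths_vary(self) -> Dict[str, bool]:
        vary: Dict[str, bool] = {}
        for stem, indices in self.layout.stems:
            counts = {
                sum(
                    1
                    for i in indices
                    if self.pair_states[t].get((stem, i)) is not None
                )
                for t in self.taxa
            }
            vary[stem] = len(counts) > 1
        return vary

    def n_indeterminate(self) -> int:
        return sum(
            1
            for t in self.taxa
            for st in self.pair_states[t].values()
            if st is not None and not st.determinate
        )

    def stem_columns(self) -> Tuple[int, ...]:
        """All annotated alignment columns (1-based), 5' and 3' members."""
        return tuple(
            sorted({s.col5 for s in self.slots} | {s.col3 for s in self.slots})
        )


def read_stem_annotation(
    annotation_path: PathLike, trna_id: Optional[str] = None
) -> List[Tuple[str, PairSlot]]:
    """Parse a stem-annotation TSV with columns
    ``trna_id  stem  pair_index  col5  col3`` (header required, columns
    1-based).  Returns ``(trna_id, PairSlot)`` rows, optionally filtered."""
    rows: List[Tuple[str, PairSlot]] = []
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"trna_id", "stem", "pair_index", "col5", "col3"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"annotation file must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            if trna_id is not None and row["trna_id"] != trna_id:
                continue
            try:
                slot = PairSlot(
                    stem=row["stem"],
                    pair_index=int(row["pair_index"]),
                    col5=int(row["col5"]),
                    col3=int(row["col3"]),
                )
            except ValueError as exc:
                raise ValueError(f"annotation row {lineno}: {exc}") from exc
            rows.append((row["trna_id"], slot))
    return rows


def read_stem_alignment(
    fasta_path: PathLike,
    annotation_path: PathLike,
    trna_id: Optional[str] = None,
) -> OrthologousStemSet:
    """Load one tRNA's orthologous FASTA alignment plus its stem annotation.

    The annotation binds each (stem, pair_index) to a 5' and a 3' alignment
    column.  Pair states are materialised per taxon; a pair whose two
    columns are both gaps is recorded as absent for that taxon, and
    ambiguity codes yield indeterminate states (counted and logged, never an
    error).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    taxa = tuple(rec.id for rec in records)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon identifiers in alignment")
    seqs = {rec.id: str(rec.seq).upper() for rec in records}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    aln_len = lengths.pop()

    if trna_id is None:
        trna_id = Path(fasta_path).stem
    rows = read_stem_annotation(annotation_path, trna_id=trna_id)
    if not rows:
        raise ValueError(f"no annotation rows for {trna_id!r} in {annotation_path}")

    slots: List[PairSlot] = []
    seen = set()
    for rowno, (_, slot) in enumerate(rows, start=1):
        key = (slot.stem, slot.pair_index)
        if key in seen:
            raise ValueError(f"duplicate annotation for pair {key} (row {rowno})")
        seen.add(key)
        for col in (slot.col5, slot.col3):
            if not (1 <= col <= aln_len):
                raise ValueError(
                    f"annotation row {rowno}: column {col} outside alignment "
                    f"of length {aln_len}"
                )
        slots.append(slot)
    slots.sort(key=lambda s: (("ac", "dh", "an", "tp").index(s.stem), s.pair_index))

    stems: List[Tuple[str, Tuple[int, ...]]] = []
    for stem in ("ac", "dh", "an", "tp"):
        idx = tuple(s.pair_index for s in slots if s.stem == stem)
        if idx:
            stems.append((stem, idx))
    layout = StemLayout(trna_id, tuple(stems))

    pair_states: Dict[str, Dict[Tuple[str, int], Optional[PairState]]] = {}
    for taxon in taxa:
        seq = seqs[taxon]
        states: Dict[Tuple[str, int], Optional[PairState]] = {}
        for slot in slots:
            b5, b3 = seq[slot.col5 - 1], seq[slot.col3 - 1]
            if b5 in "-." and b3 in "-.":
                states[(slot.stem, slot.pair_index)] = None
            else:
                states[(slot.stem, slot.pair_index)] = make_pair_state(b5, b3)
        pair_states[taxon] = states

    stem_set = OrthologousStemSet(
        trna_id=trna_id,
        taxa=taxa,
        alignment=seqs,
        layout=layout,
        slots=tuple(slots),
        pair_states=pair_states,
    )
    n_ind = stem_set.n_indeterminate()
    if n_ind:
        logger.info("%s: %d indeterminate pair states", trna_id, n_ind)
    return stem_set


def write_stem_alignment(
    stem_set: OrthologousStemSet, fasta_path: PathLike, annotation_path: PathLike
) -> None:
    """Write an :class:`OrthologousStemSet` back to FASTA + annotation TSV
    (the inverse of :func:`read_stem_alignment`)."""
    with open(fasta_path, "w") as fh:
        for taxon in stem_set.taxa:
            fh.write(f">{taxon}\n{stem_set.alignment[taxon]}\n")
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["trna_id", "stem", "pair_index", "col5", "col3"])
        for slot in stem_set.slots:
            w.writerow([stem_set.trna_id, slot.stem, slot.pair_index, slot.col5, slot.col3])


# --- trees ------------------------------------------------------------------


class Phylogeny:
    """A rooted phylogeny with stable internal node identifiers.

    Internal nodes are numbered ``N0, N1, ...`` in deterministic post-order
    (the order the Newick string lists them); tips are identified by their
    labels.  Wraps a :class:`dendropy.Tree`.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.node_by_id: Dict[str, dendropy.Node] = {}
        self.id_by_node: Dict[dendropy.Node, str] = {}
        counter = 0
        labels = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("tree has an unlabelled tip")
                nid = node.taxon.label
                labels.append(nid)
            else:
                nid = f"N{counter}"
                counter += 1
            self.node_by_id[nid] = node
            self.id_by_node[node] = nid
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_labels: Tuple[str, ...] = tuple(labels)
        self.root_id: str = self.id_by_node[tree.seed_node]

    # -- topology queries --
    def postorder_ids(self) -> List[str]:
        return [self.id_by_node[n] for n in self.tree.postorder_node_iter()]

    def preorder_ids(self) -> List[str]:
        return [self.id_by_node[n] for n in self.tree.preorder_node_iter()]

    def children(self, node_id: str) -> List[str]:
        return [self.id_by_node[c] for c in self.node_by_id[node_id].child_nodes()]

    def parent(self, node_id: str) -> Optional[str]:
        p = self.node_by_id[node_id].parent_node
        return None if p is None else self.id_by_node[p]

    def is_tip(self, node_id: str) -> bool:
        return self.node_by_id[node_id].is_leaf()

    def branch_length(self, node_id: str) -> Optional[float]:
        return self.node_by_id[node_id].edge.length

    def branches(self) -> List[Tuple[str, str]]:
        """All (parent_id, child_id) branches, post-order by child."""
        out = []
        for nid in self.postorder_ids():
            p = self.parent(nid)
            if p is not None:
                out.append((p, nid))
        return out

    def tip_descendants(self, node_id: str) -> frozenset:
        node = self.node_by_id[node_id]
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def mrca_id(self, taxa: Sequence[str]) -> str:
        node = self.tree.mrca(taxon_labels=list(taxa))
        return self.id_by_node[node]

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node
        )

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_tree(
    newick: PathLike, outgroup: Optional[Union[str, Sequence[str]]] = None
) -> Phylogeny:
    """Read a rooted Newick tree (path or literal string).

    ``outgroup`` optionally re-roots the tree on the edge subtending the
    named tip (or the MRCA of several tips).  Tip labels must be unique;
    branch lengths, if present, are preserved.
    """
    text = str(newick)
    if not text.lstrip().startswith("("):
        text = Path(newick).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"unparseable Newick: {exc}") from exc
    tree.is_rooted = True
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if outgroup is not None:
        og = [outgroup] if isinstance(outgroup, str) else list(outgroup)
        missing = set(og) - set(labels)
        if missing:
            raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
        mrca = tree.mrca(taxon_labels=og)
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return Phylogeny(tree)


def check_taxa_against_tree(taxa: Sequence[str], phylo: Phylogeny) -> None:
    """Abort with a named-taxon error if any alignment taxon is missing from
    the tree."""
    missing = set(taxa) - set(phylo.tip_labels)
    if missing:
        raise ValueError(
            f"taxa present in alignment but absent from tree: {sorted(missing)}"
        )


# --- coding sequences -------------------------------------------------------


@dataclass(frozen=True)
class CdsRecord:
    """One protein-coding gene in coding sense and frame."""

    gene: str
    sequence: str
    taxon: str = ""


def _truncate_to_codons(gene: str, seq: str) -> str:
    if len(seq) % 3:
        warnings.warn(
            f"CDS {gene}: length {len(seq)} not a multiple of 3 "
            f"(incomplete terminal codon); truncating to {len(seq) - len(seq) % 3}",
            stacklevel=3,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    return seq


def read_cds_records(path: PathLike, fmt: Optional[str] = None) -> List[CdsRecord]:
    """Read protein-coding sequences from a GenBank flatfile or a FASTA of
    CDS.

    GenBank CDS features on the reverse strand are reverse-complemented to
    coding sense.  A CDS whose length is not a multiple of 3 (mitochondrial
    incomplete stop codons completed by polyadenylation) is truncated to
    whole codons with a warning.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text()[:5000]
        fmt = "genbank" if head.lstrip().startswith("LOCUS") else "fasta"
    records: List[CdsRecord] = []
    if fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                quals = feat.qualifiers
                gene = (quals.get("gene") or quals.get("product") or ["?"])[0]
                seq = str(feat.extract(rec.seq)).upper()
                records.append(
                    CdsRecord(gene=gene, sequence=_truncate_to_codons(gene, seq),
                              taxon=rec.id)
                )
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            records.append(
                CdsRecord(gene=rec.id, sequence=_truncate_to_codons(rec.id, seq))
            )
    return records


# --- event tables -----------------------------------------------------------

_EVENT_COLUMNS = (
    "trna_id", "stem", "pair_index", "pair", "parent", "child",
    "from_state", "to_state", "kind", "fcbc_type", "changed_side",
    "is_terminal", "retained",
)


def write_event_table(events: Sequence, out_path: PathLike) -> None:
    """Write classified events (:class:`~cloverleaf.mapping.CSBPSEvent`) as a
    TSV with a stable column order; round-trips through
    :func:`read_event_table`."""
    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_EVENT_COLUMNS)
        for ev in events:
            w.writerow([
                ev.trna_id, ev.stem, ev.pair_index,
                f"{ev.pair_index}{ev.stem}",
                ev.parent_id, ev.child_id,
                f"{ev.from_state.base5}{ev.from_state.base3}",
                f"{ev.to_state.base5}{ev.to_state.base3}",
                ev.event_class.kind.value,
                ev.event_class.fcbc_type.value,
                ev.event_class.changed_side.value,
                int(ev.is_terminal), int(ev.retained),
            ])


def read_event_table(path: PathLike) -> List:
    """Read back a TSV written by :func:`write_event_table`."""
    from .mapping import CSBPSEvent  # local import to avoid a cycle

    events: List[CSBPSEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            events.append(
                CSBPSEvent(
                    trna_id=row["trna_id"],
                    stem=row["stem"],
                    pair_index=int(row["pair_index"]),
                    parent_id=row["parent"],
                    child_id=row["child"],
                    from_state=make_pair_state(*row["from_state"]),
                    to_state=make_pair_state(*row["to_state"]),
                    event_class=EventClass(
                        kind=EventKind(row["kind"]),
                        fcbc_type=FcbcType(row["fcbc_type"]),
                        changed_side=Side(row["changed_side"]),
                    ),
                    is_terminal=bool(int(row["is_terminal"])),
                    retained=bool(int(row["retained"])),
                )
            )
    return events
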