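# Methods

## The problem

Mitochondrial tRNAs fold into a cloverleaf whose four double-helical stems
(acceptor, DHU, anticodon, TΨC) must keep pairing to keep the molecule
functional. Comparative data therefore show three kinds of change in an
orthologous stem pair, collectively CSBPSs (changes of sequence in a base
pair of a stem):

* **HCBC** — hemi-compensatory base change: one base substituted, pairing
  preserved, almost always via the G•T/T•G wobble (e.g. A–T vs G•T).
* **FCBC** — fully compensatory base change: both bases substituted, both
  endpoints paired. **Type I** keeps the purine–pyrimidine orientation
  (A–T vs G–C) and can be reached by two successive HCBCs through the
  wobble. **Type II** flips the orientation (T–A vs A–T) and requires
  either a mismatch intermediate or a simultaneous double substitution.
* **Mismatch** — the derived pair is neither Watson–Crick nor wobble; with
  an ancestor→descendant direction this splits into mismatch gain and
  mismatch resolution.

`cloverleaf` classifies these changes, localises them on a reference
phylogeny, and computes the composition/skew/saturation/codon-usage
statistics used to interpret their distribution across the 22 tRNAs.

## Pair-state algebra

A pair state is the ordered duo (5′ base, 3′ base) over the DNA alphabet
(U is normalised to T on input). Of the 16 determinate states, 4 are
Watson–Crick, 2 wobble, and 10 mismatches. Orientation is the
purine/pyrimidine class of the duo; a type II verdict is exactly an
orientation swap between `pur_pyr` and `pyr_pur`. Order matters — (G,T)
and (T,G) are distinct — because HCBCs and mismatches are attributed to the
5′ or 3′ end of the pair.

IUPAC ambiguity codes and gaps are carried as *indeterminate* states, never
errors: real GenBank-derived alignments then load unchanged, and every
analysis stage skips (and counts) indeterminate pairs instead of guessing.
A pair whose two annotated columns are both gaps in one taxon is *absent
for that taxon* — variable arm lengths are biology, not mismatches.

One deliberate classification choice: a wobble→wobble double change
(G•T→T•G) is reported as `other_double`, not FCBC. It changes both bases
and stays paired, but it is not a named compensatory category, and folding
it into FCBC would silently inflate that count. FCBC endpoints may
otherwise be wobble (G–T vs T–A is a legitimate type II). `other_double`
events are excluded from CSBPS totals and reported separately.

## Boundary filter

When the DHU or TΨC arm length varies across taxa, a "mismatch" at the
loop-adjacent terminal pair of that arm is usually an artefact of aligning
stems of unequal depth. The filter removes mismatch gains/resolutions at
the terminal DHU/TΨC pair of stems whose present-pair count varies across
the alignment; HCBC and FCBC events pass through everywhere, as do
mismatches at non-boundary pairs. The filter can be disabled
(`boundary_filter=False`, CLI `--boundary-filter off`).

## Ancestral mapping

Each stem pair is reconstructed **one nucleotide site at a time** by
unordered (unit-cost) parsimony, then the two sites are composed into a
per-node pair state. A 16-state pair character would charge a double
substitution one step and fold FCBCs into single-change counts; per-site
reconstruction keeps the two substitutions of an FCBC visible as two steps.

The bottom-up pass is Hartigan's counting generalisation of Fitch: a
parent's candidate set is the set of states carried by the maximal number
of children, and each column's parsimony length accumulates
(children − max votes). This is exact for multifurcating trees and reduces
to the Fitch intersection/union rule on binary trees. Ambiguity codes enter
as candidate sets; fully missing tips contribute the full {A,C,G,T} set,
which provably leaves the length unchanged.

Ties are resolved deterministically top-down: the root takes its
lexicographically smallest candidate (A<C<G<T); each child inherits the
parent's state when it is in the child's set, otherwise its own smallest
candidate. The number of tied nodes is counted per run
(`reconstruction_ties` in the digest) so the sensitivity of tallies to
tie-breaking is auditable. Maximum-likelihood mapping is intentionally out
of scope; parsimony with a deterministic tie rule is the single engine.

One CSBPS is one branch-localised state change: the same pair changing on
k branches yields k events. Terminal events are those whose child node is a
tip. With an `ingroup` given, outgroups inform the reconstruction but only
branches whose child clade lies inside the ingroup are tallied — the branch
subtending the ingroup root is included.

A SPIC (stem position involved in change) is a (tRNA, pair, side) location
carrying at least one event; HCBCs and single-side mismatches are
attributed to the 5′ or 3′ end, FCBCs and double-change mismatches are
pair-level. Distinct transition types are reported in two conventions
(directed ordered duos, and unordered duo sets), since either convention is
defensible for "how many kinds of change occurred".

## Composition, saturation, codon usage

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed over annotated stem
positions per taxon or over a whole mtDNA strand. Zero-denominator skews
propagate as missing, not zero, so cross-taxon ranges are not artificially
shrunk; complementing a sequence negates both skews exactly (a tested
invariant). Range tables flag skews whose sign fluctuates across taxa.

Saturation is diagnosed as the mean over unordered taxon pairs of
(corrected distance − p-distance), near zero when multiple hits are rare.
The corrected distance is the **pairwise TN93 closed form** on base
frequencies pooled over the two sequences, with the two transition classes
(A↔G, C↔T) and transversions in separate log terms. TN93 is the
substitution model underlying composite-likelihood distance estimators;
the pairwise closed form keeps the diagnostic self-contained and exactly
reproducible (it matches R `ape::dist.dna(model="TN93")` to 10 decimals on
a frozen test pair). Degenerate compositions and non-positive log
arguments (full saturation) are reported as undefined and counted, never
coerced to numbers. Gapped/ambiguous columns are excluded pairwise, not
list-wise, and the comparable-site count is carried with each estimate.

Codon-family usage counts codons per thousand over the 22 tRNA families of
the vertebrate mitochondrial code (Leu split CTN→trnL1 / TTR→trnL2, Ser
split AGY→trnS1 / TCN→trnS2; AGA/AGG are stops, ATA is Met, TGA is Trp).
Stop codons are excluded (no tRNA family) and the first codon of every CDS
is excluded because initiation is read as formyl-Met regardless of the
actual start codon. CDS records whose length is not a multiple of three
(mitochondrial incomplete stop codons completed by polyadenylation) are
truncated to whole codons with a warning.

## The simulator

Each stem pair evolves as two coupled nucleotide sites under a
continuous-time process sampled exactly (Gillespie) along every branch.
A candidate single-base move is rated by its destination: `rate_paired`
(default 0.015 per unit branch length per move) when the resulting pair is
Watson–Crick or wobble, `rate_mismatch` (default 0.002) when it is a
mismatch, plus an optional simultaneous double-substitution channel
(`rate_double`, default 0). The root state of every pair is drawn from a
Watson–Crick-heavy distribution (0.22 per WC state, 0.04 per wobble,
0.004 per mismatch).

Default study conditions: a Yule tree with 46 tips (the size of a
well-sampled cetacean ingroup) scaled to total branch length 50, all 22
tRNAs with canonical layouts (acceptor 7 pairs; DHU 4, absent in trnS1;
anticodon 5 plus the extra 0-pair in trnS1/trnS2; TΨC 6). Under these
defaults a run yields roughly 600 expected events — the order of magnitude
reported for real cetacean mtDNA — so the fixture is a realistic test bed.
Alignment columns follow the cloverleaf reading order (acceptor 5′ half,
each inner arm's 5′ then reversed 3′ half, reversed acceptor 3′ half), and
the simulator writes the same FASTA/TSV/Newick formats the readers consume.

Because the simulator works per site, "type II requires a mismatch
intermediate" is an emergent property that tests assert from the event log,
not an assumption. A structural consequence worth knowing: the six paired
states form two chains, A–T — G•T — G–C and T–A — T•G — C–G, connected
*only* through mismatch states (with the double channel off). Every
orientation-flipping (type II) difference between two sequences therefore
implies a chain crossing, and among raw tip-pair differences the type II
count scales with the mismatch rate — at the default mismatch rate and deep
divergences, raw tip comparisons show type-II lookalikes at a rate a real
analysis never reports, precisely because the real analysis maps
branch-localised events on a tree instead of counting raw differences.
Tree-mapped events make type II rare again. The qualitative-regime test
(HCBC > FCBC-I ≫ FCBC-II among tip differences) accordingly runs at a
genuinely low mismatch rate (0.0002), which is the regime that hierarchy
describes.

What the simulator does *not* emulate: selection (rates are state- but not
fitness-dependent), indels and arm-length variation, rate heterogeneity
across pairs or tRNAs, base-compositional strand asymmetry, and editing.
Passing recovery tests therefore show that the mapping machinery is correct
under the neutral generating process, not that real cetacean tallies would
be recovered at the same rates.

## Recovery guarantees tested

With the double channel off, every true event changes one site, so the
number of mapped events can never exceed the number of true events
(per-column parsimony length is a lower bound on per-column true changes).
At low density — rates scaled so a pair expects ≤ 0.5 events over the whole
tree — 20 seeded 46-tip replicates recover ≥ 90% of true events at ≥ 95%
class agreement (measured: ≈ 96% and ≈ 99.9%). Recovery is scored per
(tRNA, pair, branch); class agreement over branch-pairs carrying exactly
one true and one mapped event, where the comparison is unambiguous.

## Numerical and design choices

* Annotation columns are 1-based inclusive, the way alignment figures are
  read; internal indexing is 0-based.
* Node identifiers are deterministic: tips keep their labels, internal
  nodes are numbered `N0, N1, …` in Newick post-order, so reruns and
  cross-run comparisons are byte-stable.
* The mismatch-vs-mismatch direction convention: a transition whose
  derived state is a mismatch is a gain, even if the ancestral state was
  also a mismatch; resolution requires a paired derived state.
* Sample standard deviations (n−1) in saturation summaries; means over
  defined pairs only.
* All randomness flows from a single integer seed (`numpy` Generator for
  substitutions, `random.Random` for tree shapes); identical seeds give
  identical alignments, logs and digests.
* Problem sizes in the test suite and acceptance script (46-tip trees,
  10–20 replicates, 200 parsimony oracle draws, 10,000-site distance
  simulations) were chosen as the smallest sizes at which the asserted
  tolerances are comfortably stable.

## Known limitations

* Parsimony undercounts on long branches (multiple hits collapse into net
  changes); the event tally is a lower bound, which matches how such data
  are analysed but should be remembered when comparing absolute counts.
* The TN93 closed form is per-pair; it does not pool rate parameters
  across pairs the way composite-likelihood estimators do, so saturation
  means can differ slightly from values computed with pooled estimators.
* The boundary filter needs the arm-length variation signal from the
  alignment itself; a dataset trimmed to constant-length stems will never
  trigger it.
* Intraspecific (pairwise) mode reports undirected classes only; gain vs
  resolution is meaningful only with a tree.
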