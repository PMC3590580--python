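# Methods

## Model and assumptions

The package treats a taxon as a bag of protein sequences and its
evolutionary signal as *cluster content*: which homolog families the taxon
carries. This deliberately ignores gene order, copy number, and sequence
divergence beyond the homology threshold, which is appropriate for mosaic
replicons (plasmids) where gene repertoire is the most stable comparative
signal and single-marker phylogenies are unreliable. The pipeline is fully
deterministic: identical inputs yield byte-identical outputs.

## Pairwise similarity

All pairwise decisions rest on one statistic computed from an optimal
Smith–Waterman local alignment:

    s(a, b) = match_length · identity / (len(a) + len(b))

where `match_length` counts aligned columns (gap columns included) of one
optimal traceback and `identity` is identical columns / aligned columns.
Properties: `s ∈ [0, 0.5]`; `s = 0.5` iff the sequences are identical
(full-length alignment, identity 1, denominator twice the length); `s = 0`
iff no positive-scoring local alignment exists. Putting both lengths in the
denominator keeps a long/short pair from scoring high on a short perfect
window.

The alignment engine is a Gotoh affine-gap Smith–Waterman (numba-compiled)
under BLOSUM62 with gap open 10 and gap extend 1; a gap of length `g` costs
`10 + g` (the BLAST-style convention, cross-checked in the tests against
Biopython's `PairwiseAligner` with `open_gap_score = -11`). Identity is read
off a single optimal traceback with deterministic tie-breaking (diagonal,
then vertical, then horizontal), so identical inputs always give identical
statistics. Non-standard residues (B, Z, U, O and anything else outside the
20 canonical letters) are mapped to X at parse time so every character has
matrix coverage.

### Thresholds

| parameter | default | role |
|---|---|---|
| duplicate threshold | `s ≥ 0.45` | within-taxon duplicate removal |
| homology identity | `≥ 0.40` over the aligned region | cluster edge |
| minimum alignment length | 50 columns | cluster edge guard |
| membership threshold | `s > 0.2` (strict) | cluster joining at insertion |
| acceptance threshold | best Pearson `r ≥ 0.5` | taxon insertion |
| prefilter word length | k = 4 | candidate pair screening |

The duplicate cutoff is deliberately `≥` and the membership cutoff strictly
`>`; both comparisons are implemented exactly as stated.

## k-mer prefilter

Full alignment runs only on pairs sharing at least one exact 4-mer
(inverted-index lookup). Any pair whose alignment contains a gapless
identical run of ≥ 4 residues is guaranteed to be screened in, so the
filter is effectively lossless for the divergence regimes the thresholds
accept, while eliminating the vast majority of unrelated pairs. The same
screen is applied during insertion profiling; a true member pair whose
alignment has no 4-residue identical run would be missed, but at ≥ 40%
identity over ≥ 50 columns such alignments essentially do not occur.

## Clustering

Homolog families are single-linkage connected components of the pairwise
homology graph, keeping components with ≥ 2 members; the component closure
is the deterministic completion of the pairwise relation and is invariant
to input order (ids are assigned by sorted smallest member key). Transitive
chaining can in principle merge families through intermediate sequences;
the synthetic benchmark avoids planting such chains, and real mosaic
proteins will chain by design — that is a property of single linkage, not a
bug, but worth knowing when interpreting cluster counts.

**Minimum alignment length.** The guard exists because optimal *local*
alignments of entirely unrelated random proteins reach 40% identity over
short windows at an appreciable rate: measured on random 80–300-residue
sequences, ~2% of pairs pass at 20 columns, ~0.2% at 30, and none of
20,000 pairs at 50. Because single linkage amplifies every false edge into
a merged cluster, the default is 50 columns. True homologs at the accepted
divergences align over most of their length (the generator's families are
80–300 residues long), so the guard costs no sensitivity there; clustering
very short peptides (< 50 residues) requires lowering `--min-aln-len`,
accepting the false-edge rate that comes with it.

## Distances and tree

Jaccard and Euclidean distances are computed with scipy's `pdist` on the
binary rows (for binary data `euclidean² = q + r`, the Jaccard numerator —
asserted in the tests) and wrapped in scikit-bio `DistanceMatrix`
containers. A pair of all-zero profiles gets Jaccard distance 0 with a
warning rather than NaN, keeping NJ defined.

Neighbor joining is the canonical Saitou–Nei agglomeration implemented in
the package (the documented conventions — tie-breaks and clamping — are
part of the output contract, so the algorithm is authored here and
cross-checked against scikit-bio's independent implementation in the
tests). When several
pairs minimize the Q-criterion the joined pair is the one whose smallest
leaf labels sort first; negative branch-length estimates (possible on
non-additive input) are clamped to 0 and the deficit is logged, with no
compensation on the sibling edge. The result is an unrooted tree with a
trifurcating root, serialized as Newick with six-decimal branch lengths and
labels restricted to `[A-Za-z0-9_.-]` (anything else becomes `_`, logged).

## Insertion

New proteomes never create clusters: each protein is scored against stored
cluster members (k-mer screen first) and sets the cluster's bit at
`s > 0.2`. The profile is then Pearson-correlated with every library row;
zero-variance vectors (all-zero or all-one profiles) have no defined
correlation and are reported as 0 with a warning, which makes completely
unrelated proteomes land safely below any sensible acceptance threshold.
Batch semantics follow the rebuild-once design: all newcomers are profiled
and correlated against the *original* library, accepted rows are appended
together, and distance + NJ run once on the augmented matrix. After the
rebuild, each inserted taxon's nearest library leaf by path length is
compared with its best-correlated library taxon; a mismatch is logged as a
warning for human review. The correlation threshold is a statistical screen
only — corroborating biological evidence for a placement is out of scope
for the code and left to the report's reader.

## Synthetic benchmark

The generator plants: per-family random ancestors (uniform amino-acid
composition, lengths uniform on 80–300), per-taxon family copies mutated at
a per-residue substitution rate (default 5%, i.e. ~90% pairwise identity
within a family), taxon-private random proteins, and within-taxon
duplicates (at most one substitution from their template, guaranteeing
`s ≥ 0.45`). Defaults — 6 taxa, 10 families, presence probability 0.8, 3
private proteins per taxon, duplication probability 0.3 — define the
regime used throughout the tests; one seed determines everything.

What the benchmark does *not* emulate: realistic amino-acid composition,
indels within families, horizontal transfer of partial genes, mosaicism,
or homology chains near the 40% boundary. Passing the planted-recovery
tests therefore shows the machinery is correct under clean separation
(within-family identity ≈ 90% ≫ 40% ≫ random background), not that the
thresholds are optimal for any particular real dataset.

## Numerical and degenerate-input conventions

- Q-criterion ties: resolved lexicographically (see above); scores are
  compared with a 1e-12 tolerance to keep float noise from flipping joins.
- < 3 taxa: `neighbor_join` raises; a 2-leaf tree is a single edge and not
  an NJ problem.
- Empty proteome at insertion, empty FASTA, internal stop codons: errors
  naming the offender. Trailing `*` is stripped silently.
- All-zero profile rows are kept (with a warning) so the taxon still
  appears in the tree.
- Library files are versioned JSON with sorted keys; saving the same
  objects twice is byte-identical, and version or parse mismatches raise.

## Problem sizes

The default test and acceptance workloads use 6–12 taxa with 10 planted
families (≈ 80 proteins per run), 200 oracle-checked alignments at length
≤ 30, 50 random additive matrices with 4–12 leaves, and 20 unrelated-pool
exclusion draws — sizes chosen so the full suite exercises every stage
end-to-end in a few seconds on one core while keeping every check exact.
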