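# proteodendro

Whole-proteome dendrograms from protein-cluster presence/absence profiles,
with fast insertion of new taxa via a Pearson correlation filter.

## The problem

Distance-based trees over many taxa (the motivating case: hundreds of
bacterial plasmids, which are mosaic and exchange genes horizontally) can be
built from *gene content* rather than from any single marker gene: cluster
homologous proteins across all proteomes, encode each taxon as a binary
vector of which clusters it touches, and build a neighbor-joining tree from
distances between those vectors. Because the all-against-all clustering is
the expensive step, the package also supports *augmenting* an existing tree:
a new proteome is profiled against the saved clusters only, correlated
against every stored profile, and — if it correlates well enough with
something already in the tree — appended to the matrix for a cheap NJ
rebuild.

## The method

1. **Duplicate removal** (per taxon). Pairwise similarity
   `s = L · I / (n_a + n_b)`, where `L` is the aligned-column count of the
   optimal Smith–Waterman local alignment, `I` the fractional identity over
   those columns, and `n_a`, `n_b` the sequence lengths. `s ∈ [0, 0.5]`,
   with 0.5 exactly for identical sequences; pairs with `s ≥ 0.45` are
   duplicates, grouped by connected components, longest member kept.
2. **Homolog clustering** (across taxa). An exact-match k-mer prefilter
   (word length 4) screens pairs; survivors are aligned and become edges
   when identity ≥ 40% over ≥ 50 aligned columns. Clusters are connected
   components with ≥ 2 members.
3. **Profiles.** Binary matrix `B` with `B[i, j] = 1` iff taxon `i` has a
   protein in cluster `j`.
4. **Distances.** Jaccard `d = (q + r)/(p + q + r)` (p shared presences,
   q/r one-sided) or Euclidean `d = √(q + r)`; both offered.
5. **Neighbor joining** (Saitou–Nei), deterministic tie-break, negative
   branch lengths clamped to 0; Newick output.
6. **Insertion.** New proteins join a cluster at similarity `s > 0.2`; the
   resulting profile's best Pearson correlation against the library decides
   acceptance (threshold 0.5); accepted rows are appended and NJ is rerun.

## Worked example

`python examples/01_build_tree.py` generates six synthetic proteomes with
ten planted homolog families and runs the full pipeline:

```
proteins: 78 in, 65 after duplicate removal
clusters (>=2 members): 10
profile matrix: 6 taxa x 10 clusters
newick: (((T00:0.089,T05:0.244):0.062,T01:0.121):0.021,T02:0.079,(T03:0.043,T04:0.207):0.113);
```

All ten planted families are recovered as clusters and the 13 planted
within-taxon duplicates are removed. `python examples/02_insert_taxon.py`
then inserts an exact copy of taxon T00 and one unrelated proteome:

```
pNEW: best Pearson r = 1.000 with T00 -> accepted
U00: best Pearson r = 0.000 with T00 -> rejected
pNEW placed next to T00 (path length 0.000000)
```

The copy correlates perfectly with its template and lands as its sister at
path length 0; the unrelated proteome matches no cluster and stays out.
`examples/03_similarity_scores.py` shows how the similarity score separates
identical copies (0.5), duplicates (≥ 0.45), homologs, and unrelated
sequences.

The same workflows are available from a shell:

```
proteodendro make-fixtures --out-dir fx --seed 17
proteodendro build fx/*.faa --out-dir out --metric jaccard
proteodendro insert new.faa --library out/library.json --out-dir out2
```

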