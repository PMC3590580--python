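"""Build a dendrogram from synthetic proteomes with planted homolog families.

Generates six proteomes sharing ten protein families (5% per-residue
divergence between family copies, plus private proteins and within-taxon
duplicates), then runs the full pipeline: duplicate removal, cross-taxon
homolog clustering, binary presence/absence profiles, Jaccard distances,
and neighbor joining.
"""

from proteodendro import pipeline
from proteodendro.synth_fixtures import FixtureSpec, generate

fixture = generate(FixtureSpec(seed=17))
result = pipeline.build_tree(fixture.proteomes, metric="jaccard")

n_input = sum(len(p) for p in fixture.proteomes)
n_kept = sum(len(p) for p in result.proteomes)
print(f"proteins: {n_input} in, {n_kept} after duplicate removal")
print(f"clusters (>=2 members): {len(result.clusters)}")
print(f"profile matrix: {result.matrix.n_taxa} taxa x {result.matrix.n_clusters} clusters")
print("newick:", result.tree.to_newick(decimals=3))
# Each leaf is one taxon; branch lengths are in Jaccard-distance units, so
# sister taxa share most of their cluster content.
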