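"""Insert new taxa into an existing dendrogram via the correlation filter.

Builds a library from six proteomes, then presents two newcomers: an exact
copy of library taxon T00 (should correlate at 1.0 and land as T00's
sister) and a proteome drawn from an unrelated family pool (should be
rejected at the 0.5 correlation threshold). Only the accepted taxon is
added; NJ is recomputed on the augmented profile matrix, not re-clustered.
"""

from proteodendro import pipeline
from proteodendro.sequence_io import Proteome, ProteinRecord
from proteodendro.synth_fixtures import FixtureSpec, generate

fixture = generate(FixtureSpec(seed=17))
library = pipeline.build_tree(fixture.proteomes)

copy = Proteome(
    "pNEW",
    tuple(
        ProteinRecord(r.protein_id, "pNEW", r.sequence)
        for r in fixture.proteomes[0]
    ),
)
alien = generate(FixtureSpec(seed=90017, taxon_prefix="U")).proteomes[0]

tree, reports = pipeline.insert_taxa(
    library.clusters, library.matrix, [copy, alien]
)
for rep in reports:
    verdict = "accepted" if rep.accepted else "rejected"
    print(
        f"{rep.new_taxon_id}: best Pearson r = {rep.best_value:.3f} "
        f"with {rep.best_match} -> {verdict}"
    )
nearest, dist = tree.nearest_leaf("pNEW")
print(f"pNEW placed next to {nearest} (path length {dist:.6f})")
# r = 1.0 means identical cluster content; anything below 0.5 stays out.
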