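"""End-to-end orchestration of the build and insertion workflows.

``build_tree`` runs dedup -> clustering -> profiles -> distance -> NJ and
returns every intermediate; ``insert_taxa`` profiles new proteomes against
a saved library, applies the correlation filter, and rebuilds the tree on
the augmented matrix. The CLI is a thin wrapper over these two calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .clustering import (
    DEFAULT_HOMOLOGY_IDENTITY,
    DEFAULT_MIN_ALIGNMENT_LENGTH,
    ClusterSet,
    build_clusters,
)
from .config import DEFAULT_SCORING, ScoringConfig
from .dedup import DEFAULT_DUPLICATE_THRESHOLD, dedupe_proteome
from .distance import profile_distance
from .insertion import (
    DEFAULT_ACCEPTANCE_THRESHOLD,
    DEFAULT_MEMBERSHIP_THRESHOLD,
    CorrelationReport,
    augment_tree,
    profile_new_taxon,
)
from .nj_tree import Dendrogram, neighbor_join
from .profiles import ProfileMatrix, build_profile_matrix
from .sequence_io import Proteome


@dataclass(frozen=True)
class BuildResult:
    proteomes: tuple[Proteome, ...]  # after dedup
    clusters: ClusterSet
    matrix: ProfileMatrix
    tree: Dendrogram


def build_tree(
    proteomes: Sequence[Proteome],
    params: ScoringConfig = DEFAULT_SCORING,
    dedup_threshold: float = DEFAULT_DUPLICATE_THRESHOLD,
    min_identity: float = DEFAULT_HOMOLOGY_IDENTITY,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
    metric: str = "jaccard",
) -> BuildResult:
    """Run the full build pipeline on a set of proteomes (>= 3)."""
    if len(proteomes) < 3:
        raise ValueError("tree building requires at least three proteomes")
    deduped = tuple(dedupe_proteome(p, dedup_threshold, params) for p in proteomes)
    clusters = build_clusters(deduped, params, min_identity, min_alignment_length)
    matrix = build_profile_matrix(clusters, deduped)
    tree = neighbor_join(profile_distance(matrix, metric))
    return BuildResult(proteomes=deduped, clusters=clusters, matrix=matrix, tree=tree)


def insert_taxa(
    clusters: ClusterSet,
    library: ProfileMatrix,
    new_proteomes: Sequence[Proteome],
    params: ScoringConfig = DEFAULT_SCORING,
    membership_threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD,
    threshold: float = DEFAULT_ACCEPTANCE_THRESHOLD,
    metric: str = "jaccard",
) -> tuple[Dendrogram, list[CorrelationReport]]:
    """Profile new proteomes against the library and rebuild the tree.

    Batch semantics: every proteome is profiled and correlated against the
    original library; all accepted rows are appended before the single
    rebuild.
    """
    profiles = [
        profile_new_taxon(p, clusters, params, membership_threshold)
        for p in new_proteomes
    ]
    return augment_tree(library, profiles, metric=metric, threshold=threshold)
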