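"""Insertion of new taxa into an existing dendrogram via correlation
filtering.

Rebuilding a large tree from scratch for every newly sequenced taxon is
wasteful; instead the new proteome is profiled against the saved cluster
library (a protein joins a cluster when its similarity score against any
member exceeds 0.2), the resulting binary profile is correlated (Pearson)
against every library profile, and the taxon is accepted when its best
correlation reaches the acceptance threshold (default 0.5). Accepted
profiles are appended to the binary matrix and the distance matrix and NJ
tree are recomputed on the augmented matrix — topology is refreshed, but
the expensive all-against-all clustering is not.

Proteins matching no existing cluster are ignored: the library represents
the diversity seen at build time, and a full rebuild is the remedy when it
grows stale. The correlation threshold is a statistical screen only; any
additional biological evidence for membership is left to human review of
the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import _kmers, pair_similarity
from .clustering import ClusterSet
from .config import DEFAULT_SCORING, ScoringConfig
from .distance import profile_distance
from .nj_tree import Dendrogram, neighbor_join
from .profiles import BinaryProfile, ProfileMatrix
from .sequence_io import Proteome

logger = logging.getLogger(__name__)

DEFAULT_MEMBERSHIP_THRESHOLD = 0.2
DEFAULT_ACCEPTANCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class CorrelationReport:
    """Outcome of correlating one new taxon against the filter library."""

    new_taxon_id: str
    coefficients: pd.Series  # indexed by library taxon_id
    best_match: str
    best_value: float
    accepted: bool
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "new_taxon_id": self.new_taxon_id,
                "library_taxon_id": self.coefficients.index,
                "pearson_r": self.coefficients.values,
                "best": self.coefficients.index == self.best_match,
                "accepted": self.accepted,
                "threshold": self.threshold,
            }
        )


def profile_new_taxon(
    proteome: Proteome,
    clusters: ClusterSet,
    params: ScoringConfig = DEFAULT_SCORING,
    membership_threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD,
) -> BinaryProfile:
    """Presence/absence profile of a new proteome over the library clusters.

    Bit j is set iff some protein of the proteome scores strictly above
    ``membership_threshold`` (similarity score) against some member of
    cluster j. A protein may set bits of several clusters. The k-mer
    prefilter screens protein/member pairs before alignment, as during
    clustering.
    """
    if len(proteome) == 0:
        raise ValueError(f"proteome {proteome.taxon_id!r} is empty")
    k = params.kmer_length
    new_kmers = [(_kmers(rec.sequence, k), rec.sequence) for rec in proteome]
    bits = np.zeros(len(clusters), dtype=np.uint8)
    for cluster in clusters.clusters:
        hit = False
        for _, member_seq in clusters.member_sequences(cluster):
            member_kmers = _kmers(member_seq, k)
            for prot_kmers, prot_seq in new_kmers:
                if not (prot_kmers & member_kmers):
                    continue
                score = pair_similarity(prot_seq, member_seq, params)
                if score > membership_threshold:
                    hit = True
                    break
            if hit:
                break
        bits[cluster.cluster_id] = 1 if hit else 0
    return BinaryProfile(taxon_id=proteome.taxon_id, bits=bits)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlate(
    profile: BinaryProfile,
    library: ProfileMatrix,
    threshold: float = DEFAULT_ACCEPTANCE_THRESHOLD,
) -> CorrelationReport:
    """Pearson correlation of a new profile against every library profile.

    A zero-variance vector (all-zero or all-one profile) has no defined
    correlation; such comparisons are reported as 0 with a warning. The
    taxon is accepted when the best coefficient reaches ``threshold``.
    """
    if len(profile) != library.n_clusters:
        raise ValueError(
            f"profile has {len(profile)} bits but the library has "
            f"{library.n_clusters} clusters"
        )
    x = profile.bits.astype(float)
    degenerate = x.std() == 0.0
    if degenerate:
        logger.warning(
            "profile of %s has zero variance; correlations reported as 0",
            profile.taxon_id,
        )
    coeffs = {}
    for taxon, row in zip(library.taxa, library.values):
        y = row.astype(float)
        if not degenerate and y.std() == 0.0:
            logger.warning(
                "library profile of %s has zero variance; correlation "
                "reported as 0", taxon,
            )
        coeffs[taxon] = _pearson(x, y)
    series = pd.Series(coeffs, name=profile.taxon_id)
    best_match = series.idxmax()
    # deterministic tie-break: smallest taxon_id among maxima
    maxima = series[series == series.max()].index
    best_match = sorted(maxima)[0]
    best_value = float(series[best_match])
    return CorrelationReport(
        new_taxon_id=profile.taxon_id,
        coefficients=series,
        best_match=best_match,
        best_value=best_value,
        accepted=best_value >= threshold,
        threshold=threshold,
    )


def augment_tree(
    library: ProfileMatrix,
    new_profiles: Sequence[BinaryProfile],
    metric: str = "jaccard",
    threshold: float = DEFAULT_ACCEPTANCE_THRESHOLD,
) -> tuple[Dendrogram, list[CorrelationReport]]:
    """Insert accepted new taxa into the tree and rebuild it.

    All profiles are correlated against the ORIGINAL library; the accepted
    ones are appended together as rows, and distance + NJ are recomputed on
    the augmented matrix (batch semantics). Rejected profiles are reported
    but not inserted; with zero acceptances the returned tree is simply the
    library tree. As a sanity check, each inserted taxon's nearest leaf by
    path length is compared with its best-correlated library taxon and a
    mismatch is logged as a warning.
    """
    reports = [correlate(p, library, threshold) for p in new_profiles]
    accepted = [
        p for p, rep in zip(new_profiles, reports) if rep.accepted
    ]
    for p in accepted:
        if p.taxon_id in library.taxa:
            raise ValueError(
                f"new taxon_id {p.taxon_id!r} collides with a library taxon"
            )
    augmented = library.with_rows(accepted)
    tree = neighbor_join(profile_distance(augmented, metric))
    for p, rep in zip(new_profiles, reports):
        if not rep.accepted:
            logger.info(
                "taxon %s rejected (best r=%.3f < %.2f)",
                p.taxon_id, rep.best_value, threshold,
            )
            continue
        nearest, _ = _nearest_original(tree, p.taxon_id, set(library.taxa))
        if nearest != rep.best_match:
            logger.warning(
                "inserted taxon %s: nearest library leaf %s differs from "
                "best-correlated taxon %s", p.taxon_id, nearest, rep.best_match,
            )
    return tree, reports


def _nearest_original(
    tree: Dendrogram, taxon: str, original: set[str]
) -> tuple[str, float]:
    dm = tree.leaf_distances()
    row = dm[taxon]
    best = min(
        (d, other)
        for other, d in zip(dm.ids, row)
        if other != taxon and other in original
    )
    return best[1], best[0]
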