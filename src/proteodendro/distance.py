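"""Taxon-taxon distances from the binary profile matrix.

Two metrics are offered, and practice is to inspect trees under both:

* Jaccard: d(i, j) = (q + r) / (p + q + r), where p counts clusters present
  in both taxa, and q and r count clusters private to taxon i and taxon j
  respectively. A pair of all-zero profiles is assigned distance 0
  (identical emptiness) with a warning.
* Euclidean: d(i, j) = sqrt(q + r) on binary rows, i.e. the square root of
  the Hamming distance; no normalization by profile length is applied.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

METRICS = ("jaccard", "euclidean")


def jaccard_distance(matrix: ProfileMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distance between taxon profiles."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least two taxa for a distance matrix")
    bits = matrix.values.astype(bool)
    zero_rows = ~bits.any(axis=1)
    if zero_rows.sum() >= 2:
        logger.warning(
            "%d all-zero profiles: their mutual Jaccard distance is defined as 0",
            int(zero_rows.sum()),
        )
    d = squareform(pdist(bits, metric="jaccard"))
    return DistanceMatrix(d, ids=list(matrix.taxa))


def euclidean_distance(matrix: ProfileMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between binary taxon profiles."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least two taxa for a distance matrix")
    d = squareform(pdist(matrix.values.astype(float), metric="euclidean"))
    return DistanceMatrix(d, ids=list(matrix.taxa))


def profile_distance(matrix: ProfileMatrix, metric: str = "jaccard") -> DistanceMatrix:
    """Dispatch on metric name ('jaccard' or 'euclidean')."""
    if metric == "jaccard":
        return jaccard_distance(matrix)
    if metric == "euclidean":
        return euclidean_distance(matrix)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def to_phylip(dm: DistanceMatrix) -> str:
    """Square PHYLIP rendering of a distance matrix."""
    lines = [f"{len(dm.ids):5d}"]
    for name, row in zip(dm.ids, dm.data):
        lines.append(
            f"{name:<10s}  " + " ".join(f"{x:.6f}" for x in row)
        )
    return "\n".join(lines) + "\n"


def to_tsv(dm: DistanceMatrix) -> str:
    """Tab-separated rendering with a header row."""
    header = "\t".join(["taxon"] + list(dm.ids))
    lines = [header]
    for name, row in zip(dm.ids, dm.data):
        lines.append("\t".join([name] + [f"{x:.6f}" for x in row]))
    return "\n".join(lines) + "\n"
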