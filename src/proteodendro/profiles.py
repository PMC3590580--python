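"""Binary presence/absence profiles over homolog clusters.

Each taxon is encoded as a 0/1 vector with one bit per cluster: bit j is 1
iff the taxon contributes at least one protein to cluster j (presence, not
count). Stacking all taxa gives the taxa x clusters profile matrix — the
correlation filter library used both for tree building and for placing new
taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .sequence_io import Proteome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryProfile:
    """Per-taxon presence/absence bit vector over the cluster set."""

    taxon_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("profile bits must be a flat 0/1 vector")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class ProfileMatrix:
    """Taxa x clusters binary matrix; row order matches ``taxa``."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        if values.ndim != 2 or values.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match the taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon_ids in profile matrix")
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "values", values)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    def row(self, taxon_id: str) -> BinaryProfile:
        return BinaryProfile(taxon_id, self.values[self.taxa.index(taxon_id)])

    def profiles(self) -> list[BinaryProfile]:
        return [BinaryProfile(t, self.values[i]) for i, t in enumerate(self.taxa)]

    def with_rows(self, profiles: Sequence[BinaryProfile]) -> "ProfileMatrix":
        """A new matrix with the given profiles appended as rows."""
        if not profiles:
            return self
        for p in profiles:
            if len(p) != self.n_clusters:
                raise ValueError(
                    f"profile {p.taxon_id!r} has {len(p)} bits, expected "
                    f"{self.n_clusters}"
                )
        return ProfileMatrix(
            taxa=self.taxa + tuple(p.taxon_id for p in profiles),
            values=np.vstack([self.values] + [p.bits for p in profiles]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.taxa),
            columns=[f"c{j}" for j in range(self.n_clusters)],
        )


def build_profile_matrix(
    clusters: ClusterSet, proteomes: Sequence[Proteome] | Iterable[Proteome]
) -> ProfileMatrix:
    """Incidence matrix of taxa over clusters.

    Entry (i, j) is 1 iff any protein of taxon i belongs to cluster j. A
    taxon with no clustered protein keeps its all-zero row, with a warning.
    """
    proteomes = list(proteomes)
    taxa = tuple(p.taxon_id for p in proteomes)
    membership = clusters.membership()
    values = np.zeros((len(taxa), len(clusters)), dtype=np.uint8)
    for i, proteome in enumerate(proteomes):
        for rec in proteome:
            j = membership.get(rec.key)
            if j is not None:
                values[i, j] = 1
    for i, taxon in enumerate(taxa):
        if len(clusters) and not values[i].any():
            logger.warning("taxon %s has an all-zero profile", taxon)
    return ProfileMatrix(taxa=taxa, values=values)
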