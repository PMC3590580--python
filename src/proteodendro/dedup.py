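"""Removal of duplicate proteins within a proteome.

Two proteins of the same taxon are duplicates when their similarity score
reaches the duplicate threshold (default 0.45; identical sequences score
0.5). Duplicate groups are the connected components of the >= threshold
graph, so the result does not depend on comparison order; from each group
the longest sequence is retained, ties broken by input order.
Cross-taxon pairs are never compared.
"""

from __future__ import annotations

import logging

from .alignment import candidate_pairs, pair_similarity
from .config import DEFAULT_SCORING, ScoringConfig
from .sequence_io import Proteome
from .union_find import UnionFind

logger = logging.getLogger(__name__)

DEFAULT_DUPLICATE_THRESHOLD = 0.45


def duplicate_groups(
    proteome: Proteome,
    threshold: float = DEFAULT_DUPLICATE_THRESHOLD,
    params: ScoringConfig = DEFAULT_SCORING,
) -> list[list[int]]:
    """Connected components of the within-proteome duplicate graph.

    Returns lists of record indices (input order); every component with a
    single member is a non-duplicated protein.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("duplicate threshold must lie in (0, 0.5]")
    index_of = {rec.key: i for i, rec in enumerate(proteome.records)}
    uf = UnionFind(len(proteome.records))
    for key_a, key_b in candidate_pairs(proteome.records, params.kmer_length):
        ia, ib = index_of[key_a], index_of[key_b]
        score = pair_similarity(
            proteome.records[ia].sequence, proteome.records[ib].sequence, params
        )
        if score >= threshold:
            uf.union(ia, ib)
    return uf.components()


def dedupe_proteome(
    proteome: Proteome,
    threshold: float = DEFAULT_DUPLICATE_THRESHOLD,
    params: ScoringConfig = DEFAULT_SCORING,
) -> Proteome:
    """Return the proteome with duplicate proteins removed.

    From each duplicate group the longest sequence is kept (ties: first in
    input order); the output preserves the input order of the retained
    records. Idempotent: running it twice changes nothing further.
    """
    groups = duplicate_groups(proteome, threshold, params)
    keep: set[int] = set()
    removed = 0
    for group in groups:
        winner = max(group, key=lambda i: (len(proteome.records[i].sequence), -i))
        keep.add(winner)
        removed += len(group) - 1
    if removed:
        logger.info(
            "proteome %s: removed %d duplicate protein(s) of %d",
            proteome.taxon_id, removed, len(proteome),
        )
    return Proteome(
        taxon_id=proteome.taxon_id,
        records=tuple(rec for i, rec in enumerate(proteome.records) if i in keep),
    )
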