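"""Smith-Waterman local alignment, the pairwise similarity score, and the
exact-match k-mer prefilter.

The alignment engine is a Gotoh-style affine-gap Smith-Waterman with a full
traceback, JIT-compiled with numba. A gap of length ``g`` costs
``gap_open + g * gap_extend`` (the BLAST convention). Identity is the
fraction of identical columns over all aligned columns of one optimal local
alignment, gap columns included; traceback ties are broken by preferring a
diagonal move, then a vertical (gap in the second sequence), then a
horizontal move, so results are deterministic across runs and platforms.

The similarity score of a sequence pair is

    match_length * identity / (len_a + len_b)

which is 0 when no positive-scoring local alignment exists and attains its
maximum, exactly 0.5, when the two sequences are identical.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .config import DEFAULT_SCORING, ScoringConfig
from .sequence_io import ProteinRecord

PairKey = tuple[tuple[str, str], tuple[str, str]]


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one optimal local alignment.

    ``match_length`` counts aligned columns (substitutions and gaps);
    ``identity`` is identical columns / aligned columns, in [0, 1];
    ``raw_score`` is the optimal score in substitution-matrix units.
    ``match_length == 0`` iff no positive-scoring local alignment exists.
    """

    match_length: int
    identity: float
    raw_score: float


@lru_cache(maxsize=None)
def _matrix_tables(matrix_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Substitution matrix as a dense array plus an ASCII lookup table.

    Characters absent from the matrix alphabet score as X.
    """
    mat = substitution_matrices.load(matrix_name)
    alphabet = str(mat.alphabet)
    scores = np.asarray(mat, dtype=np.float64)
    x_index = alphabet.index("X") if "X" in alphabet else 0
    lut = np.full(128, x_index, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    return scores, lut


def encode(sequence: str, matrix_name: str = DEFAULT_SCORING.matrix_name) -> np.ndarray:
    """Encode an amino-acid string as substitution-matrix row indices."""
    _, lut = _matrix_tables(matrix_name)
    return lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_kernel(a, b, scores, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = a.shape[0], b.shape[0]
    open_cost = gap_open + gap_extend
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    # ptr_h: 0 stop, 1 diagonal, 2 vertical (gap in b), 3 horizontal (gap in a)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extended
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            diag = H[i - 1, j - 1] + scores[a[i - 1], b[j - 1]]
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0
    # traceback: state 0 = H, 2 = F (vertical), 3 = E (horizontal)
    i, j = bi, bj
    state = 0
    cols = 0
    matches = 0
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            cols += 1
            p = ptr_f[i, j]
            i -= 1
            state = 2 if p == 1 else 0
        else:
            cols += 1
            p = ptr_e[i, j]
            j -= 1
            state = 3 if p == 1 else 0
    return best, cols, matches


def smith_waterman(
    a: str, b: str, params: ScoringConfig = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal local alignment of two amino-acid strings.

    Returns the optimal Smith-Waterman score under the configured
    substitution matrix and affine gap penalties, with identity and aligned
    length taken from one optimal traceback. If no positive-scoring local
    alignment exists the result has ``match_length == 0``.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    scores, _ = _matrix_tables(params.matrix_name)
    raw, cols, matches = _sw_kernel(
        encode(a, params.matrix_name),
        encode(b, params.matrix_name),
        scores,
        float(params.gap_open),
        float(params.gap_extend),
    )
    identity = matches / cols if cols else 0.0
    return AlignmentResult(match_length=int(cols), identity=identity, raw_score=float(raw))


def similarity_score(len_a: int, len_b: int, aln: AlignmentResult) -> float:
    """Length-normalized similarity of an aligned pair, in [0, 0.5].

    Defined as ``match_length * identity / (len_a + len_b)``. Two identical
    sequences score exactly 0.5; including both lengths in the denominator
    keeps a large length difference from biasing the score.
    """
    return aln.match_length * aln.identity / (len_a + len_b)


def pair_similarity(a: str, b: str, params: ScoringConfig = DEFAULT_SCORING) -> float:
    """Align two sequences and return their similarity score."""
    return similarity_score(len(a), len(b), smith_waterman(a, b, params))


def record_similarity(
    reference: ProteinRecord,
    candidate: ProteinRecord,
    params: ScoringConfig = DEFAULT_SCORING,
) -> float:
    """Similarity score between two protein records."""
    return pair_similarity(reference.sequence, candidate.sequence, params)


def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def candidate_pairs(
    records: Sequence[ProteinRecord] | Iterable[ProteinRecord], k: int = 4
) -> set[PairKey]:
    """Unordered record pairs sharing at least one exact common k-mer.

    Implemented with an inverted k-mer index, this screen is a superset of
    any pair whose alignment contains a gapless identical run of length
    >= k, so downstream alignment only runs on promising pairs. Pairs are
    returned as sorted ``((taxon_id, protein_id), (taxon_id, protein_id))``
    tuples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(records)
    index: dict[str, list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        for kmer in _kmers(rec.sequence, k):
            index[kmer].append(idx)
    pair_ids: set[tuple[int, int]] = set()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i, ia in enumerate(bucket):
            for ib in bucket[i + 1 :]:
                pair_ids.add((ia, ib) if ia < ib else (ib, ia))
    out: set[PairKey] = set()
    for ia, ib in pair_ids:
        ka, kb = records[ia].key, records[ib].key
        out.add((ka, kb) if ka <= kb else (kb, ka))
    return out
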