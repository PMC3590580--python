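"""Independent reference implementations used only to check the package.

These are deliberately naive: an unoptimized full-DP affine-gap local
alignment scorer, a quadratic common-k-mer scan, and a recursive additive
distance computation on randomly generated trees.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Best local alignment score; a gap of length g costs open + g*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def common_kmer_pairs(records, k: int):
    """All-pairs quadratic scan for a shared exact substring of length k."""
    out = set()
    for ra, rb in itertools.combinations(records, 2):
        kmers_a = {ra.sequence[i : i + k] for i in range(len(ra.sequence) - k + 1)}
        if any(rb.sequence[i : i + k] in kmers_a for i in range(len(rb.sequence) - k + 1)):
            key = tuple(sorted((ra.key, rb.key)))
            out.add(key)
    return out


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random edge-weighted binary tree plus its exact leaf distances.

    Returns (newick, leaf_names, distance_matrix) with names sorted and the
    matrix in that order. Distances are computed by recursion on the tree,
    independently of any package code.
    """
    names = [f"L{i}" for i in range(n_leaves)]
    dist: dict[frozenset, float] = {}

    def build(leaves: list[str]):
        # returns (newick, {leaf: distance to this node's root})
        if len(leaves) == 1:
            return leaves[0], {leaves[0]: 0.0}
        order = list(leaves)
        rng.shuffle(order)
        k = int(rng.integers(1, len(order)))
        left, dl = build(order[:k])
        right, dr = build(order[k:])
        bl = float(rng.uniform(0.1, 1.0))
        br = float(rng.uniform(0.1, 1.0))
        dl = {name: d + bl for name, d in dl.items()}
        dr = {name: d + br for name, d in dr.items()}
        for na, da in dl.items():
            for nb, db in dr.items():
                dist[frozenset((na, nb))] = da + db
        newick = f"({left}:{bl:.9f},{right}:{br:.9f})"
        return newick, {**dl, **dr}

    newick, _ = build(names)
    matrix = np.zeros((n_leaves, n_leaves))
    ordered = sorted(names)
    for (i, na), (j, nb) in itertools.combinations(enumerate(ordered), 2):
        matrix[i, j] = matrix[j, i] = dist[frozenset((na, nb))]
    return newick + ";", ordered, matrix


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) via dendropy."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=tns,
        rooting="force-unrooted",
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=tns,
        rooting="force-unrooted",
    )
    return treecompare.symmetric_difference(ta, tb)
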