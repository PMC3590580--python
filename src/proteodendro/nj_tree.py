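"""Neighbor-joining dendrogram construction.

Canonical Saitou-Nei neighbor joining: at each step join the pair (i, j)
minimizing Q(i, j) = (n - 2) d(i, j) - r_i - r_j (r_i the row sum), attach
both at branch lengths d(i,j)/2 +- (r_i - r_j)/(2(n - 2)), and reduce the
matrix with d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2. The output is an
unrooted tree represented with a trifurcating root. NJ is consistent: on an
additive distance matrix it recovers the generating topology exactly and
its path lengths reproduce the input distances.

Determinism: when several pairs minimize Q, the pair whose (smallest-leaf,
smallest-leaf) label pair sorts lexicographically first is joined.
Negative branch length estimates are clamped to zero and the clamped
deficit is logged; no length is transferred to the sibling edge.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class Clade:
    """A node of the dendrogram: leaf (has a name) or internal."""

    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Unrooted NJ tree; the root is a trifurcation (or the 2-leaf stub)."""

    root: Clade

    def leaves(self) -> list[Clade]:
        out: list[Clade] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_newick(self, decimals: int = 6, label_fn=None) -> str:
        label_fn = label_fn or (lambda s: s)

        def fmt(node: Clade) -> str:
            if node.is_leaf:
                body = label_fn(node.name)
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            return f"{body}:{node.length:.{decimals}f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        paths: dict[str, float] = {}
        dists: dict[frozenset[str], float] = {}

        def walk(node: Clade, acc: float) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, acc)]
            below: list[list[tuple[str, float]]] = []
            for child in node.children:
                below.append(walk(child, child.length))
            for la, lb in itertools.combinations(range(len(below)), 2):
                for name_a, da in below[la]:
                    for name_b, db in below[lb]:
                        dists[frozenset((name_a, name_b))] = da + db
            return [(name, d + acc) for sub in below for name, d in sub]

        walk(self.root, 0.0)
        names = sorted(self.leaf_names())
        mat = np.zeros((len(names), len(names)))
        for (ia, a), (ib, b) in itertools.combinations(enumerate(names), 2):
            mat[ia, ib] = mat[ib, ia] = dists[frozenset((a, b))]
        return DistanceMatrix(mat, ids=names)

    def nearest_leaf(self, name: str) -> tuple[str, float]:
        """Closest other leaf by path length (ties: lexicographic)."""
        dm = self.leaf_distances()
        row = dm[name]
        best = min(
            (d, other) for other, d in zip(dm.ids, row) if other != name
        )
        return best[1], best[0]


def neighbor_join(dm: DistanceMatrix) -> Dendrogram:
    """Build an unrooted NJ dendrogram from a distance matrix.

    Requires at least three taxa; the matrix must be symmetric with a zero
    diagonal (enforced by the DistanceMatrix container).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(
            "neighbor joining needs >= 3 taxa; for 2 taxa the tree is the "
            "single edge between them"
        )
    d = dm.data.astype(float).copy()
    nodes: list[Clade] = [Clade(name=t) for t in dm.ids]
    # tie-break key of an active node: its smallest leaf label
    keys: list[str] = list(dm.ids)
    active = list(range(n))

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.info("clamped negative branch length %.3g at %s", length, context)
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best_q = np.inf
        best_pair: tuple[int, int] | None = None
        best_key: tuple[str, str] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_key is None or key < best_key)
                ):
                    best_q = q
                    best_pair = (i, j)
                    best_key = key
        i, j = best_pair
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = clamp(li, f"join({keys[i]},{keys[j]})")
        nodes[j].length = clamp(lj, f"join({keys[i]},{keys[j]})")
        parent = Clade(children=[nodes[i], nodes[j]])
        # reduce: reuse slot i for the new node, drop j
        for k in active:
            if k in (i, j):
                continue
            dik = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = dik
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    a, b, c = active
    # final trifurcation lengths from the three-point formulas
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    order = sorted(((keys[x], x) for x in (a, b, c)))
    lengths = {a: la, b: lb, c: lc}
    children = []
    for key, x in order:
        nodes[x].length = clamp(lengths[x], f"root({key})")
        children.append(nodes[x])
    return Dendrogram(root=Clade(children=children))
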