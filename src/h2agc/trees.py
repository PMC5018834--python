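"""Distance-based phylogenetics: neighbor joining and clustering scores.

The neighbor-joining implementation is deliberately explicit (Q-matrix
agglomeration with lexicographic tie-breaking on sorted leaf-label tuples) so
its behaviour is reproducible and checkable against an independent oracle;
newick serialization and cophenetic (tip-to-tip path) distances go through
scikit-bio's TreeNode.

For an additive distance matrix neighbor joining recovers the generating
unrooted topology exactly; on the near-identical histone isoform sequences it
is applied to, p-distances are close to additive and the method is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)


def p_distance_matrix(labels: Sequence[str], rows: Sequence[str]) -> DistanceMatrix:
    """Pairwise p-distance matrix from aligned rows (see isoforms.p_distance)."""
    from .isoforms import p_distance

    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = p_distance(rows[i], rows[j])
    return DistanceMatrix(tuple(labels), d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    sorted pair of cluster keys (a cluster's key is the sorted tuple of its
    leaf labels), so the output is independent of label order. Negative
    branch lengths are clamped to zero. The returned tree is unrooted in the
    usual NJ sense: the root is the final three-way (or two-way) join.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    if len(set(dm.labels)) != n:
        raise ValueError("duplicate labels")

    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    keys: list[tuple[str, ...]] = [(label,) for label in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> TreeNode:
        parent = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.extend([nodes[i], nodes[j]])
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * d[i, j] + (r[a] - r[b]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = join(i, j, li, lj)
        # distances from the new node to every other active node
        new_d = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_d[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d[:-1]
        d[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        keys.append(tuple(sorted(keys[i] + keys[j])))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            nodes[idx].length = max(ln, 0.0)
            root.append(nodes[idx])
    else:  # two clusters left (can happen only for n == small after joins)
        i, j = active
        nodes[i].length = max(d[i, j] / 2, 0.0)
        nodes[j].length = max(d[i, j] / 2, 0.0)
        root.extend([nodes[i], nodes[j]])
    return root


def cophenetic_distances(tree: TreeNode):
    """Tip-to-tip path-length distances (scikit-bio DistanceMatrix)."""
    return tree.tip_tip_distances()


def type_clustering_score(
    tree: TreeNode, labels: Mapping[str, str]
) -> float | None:
    """Between/within-category mean cophenetic distance ratio.

    ``labels`` maps every leaf name to a category (e.g. SER40/ALA40). A score
    above 1 means leaves of the same category sit closer together in the tree
    than leaves of different categories — type-dependent clustering. Returns
    None when either category has fewer than two leaves.
    """
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing[:5]}")
    cats = sorted(set(labels[t] for t in tips))
    if len(cats) != 2:
        raise ValueError(f"expected exactly 2 categories, got {cats}")
    counts = {c: sum(1 for t in tips if labels[t] == c) for c in cats}
    if min(counts.values()) < 2:
        return None
    dmat = tree.tip_tip_distances()
    within, between = [], []
    for a, b in combinations(tips, 2):
        (within if labels[a] == labels[b] else between).append(dmat[a, b])
    w = float(np.mean(within))
    bt = float(np.mean(between))
    if w == 0 and bt == 0:
        return 1.0
    if w == 0:
        return float("inf")
    return bt / w
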