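"""Agglomerative clustering of entities on their slice-score vectors.

Distances are Euclidean on the (n_entities × n_slices) slice-score matrix.
Agglomeration follows the Lance–Williams recurrence with six linkage
methods matching the classic hclust family:

single      d(AB,C) = min(d(A,C), d(B,C))
complete    d(AB,C) = max(d(A,C), d(B,C))
average     d(AB,C) = (nA·d(A,C) + nB·d(B,C)) / (nA+nB)          (UPGMA)
mcquitty    d(AB,C) = (d(A,C) + d(B,C)) / 2                      (WPGMA)
centroid    on squared distances:
            d² = (nA·dAC² + nB·dBC²)/(nA+nB) − nA·nB·dAB²/(nA+nB)²
ward        Ward's minimum-variance criterion on squared distances
            (the "D2" convention: raw Euclidean input, heights reported
            back on the distance scale);
            d² = ((nA+nC)·dAC² + (nB+nC)·dBC² − nC·dAB²)/(nA+nB+nC)

At each step the pair at minimum current distance merges; exact ties break
on the smallest (left, right) pair of cluster representatives, a cluster
being represented by its smallest original entity index.  Heights are
non-decreasing for the monotone methods; centroid may produce inversions.

Node ids follow the usual convention: leaves are 0..n-1, the k-th merge
creates node n+k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LINKAGE_METHODS",
    "Dendrogram",
    "ClusterAssignment",
    "euclidean_distances",
    "linkage",
    "cut_dendrogram",
    "select_branch",
    "auto_color",
]

LINKAGE_METHODS = ("single", "complete", "average", "mcquitty", "centroid", "ward")

MONOTONE_METHODS = ("single", "complete", "average", "mcquitty", "ward")

#: deterministic categorical palette for branch coloring (colorblind-aware)
PALETTE = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#C7C7C7", "#DBDB8D", "#9EDAE5",
)

NEUTRAL_COLOR = "#666666"


class ClusteringError(ValueError):
    pass


@dataclass
class Dendrogram:
    """Merge tree: n-1 records of (left node, right node, height)."""

    merges: np.ndarray  # (n-1, 2) int node ids
    heights: np.ndarray  # (n-1,) floats, distance scale
    n_leaves: int
    method: str
    entity_ids: list[str] | None = None

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        return tuple(self.merges[node - self.n_leaves])

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else float(self.heights[node - self.n_leaves])

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices of the subtree, left-to-right."""
        if node >= 2 * self.n_leaves - 1 or node < 0:
            raise ClusteringError(f"unknown node id: {node}")
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            ch = self.children(v)
            if ch is None:
                out.append(v)
            else:
                stack.extend((ch[1], ch[0]))
        return out

    @property
    def leaf_order(self) -> list[int]:
        """Crossing-free drawing order (see _ordered_children)."""
        return self.leaves_under(self.root)

    def min_leaf(self, node: int) -> int:
        return min(self.leaves_under(node))

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − node height."""
        names = self.entity_ids or [str(i) for i in range(self.n_leaves)]

        def rec(node: int, parent_h: float) -> str:
            h = self.node_height(node)
            bl = max(parent_h - h, 0.0)
            ch = self.children(node)
            if ch is None:
                return f"{_newick_escape(names[node])}:{bl:.10g}"
            return f"({rec(ch[0], h)},{rec(ch[1], h)}):{bl:.10g}"

        h = self.node_height(self.root)
        ch = self.children(self.root)
        return f"({rec(ch[0], h)},{rec(ch[1], h)});"


def _newick_escape(name: str) -> str:
    if any(c in name for c in " (),:;'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-entity cluster id, 1..k
    k: int
    origin: str  # hier_cut | hier_branch | kmeans

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) != self.k:
            raise ClusteringError(
                f"labels take {len(np.unique(self.labels))} values, expected k={self.k}"
            )


def euclidean_distances(slice_scores: np.ndarray) -> np.ndarray:
    """Condensed pairwise Euclidean distances (same layout as pdist)."""
    X = np.asarray(slice_scores, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ClusteringError("need at least 2 entities")
    sq = (X[:, None, :] - X[None, :, :]) ** 2
    D = np.sqrt(sq.sum(axis=2))
    return D[np.triu_indices(n, k=1)]


def _squareform(condensed: np.ndarray) -> np.ndarray:
    m = condensed.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ClusteringError("invalid condensed distance length")
    D = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    D[iu] = condensed
    D += D.T
    return D


def linkage(
    condensed: np.ndarray,
    method: str,
    entity_ids: list[str] | None = None,
) -> Dendrogram:
    """Lance–Williams agglomeration of a condensed distance matrix."""
    if method not in LINKAGE_METHODS:
        raise ClusteringError(
            f"unknown method {method!r}; choose from {LINKAGE_METHODS}"
        )
    squared = method in ("centroid", "ward")
    D = _squareform(np.asarray(condensed, dtype=float))
    n = D.shape[0]
    if squared:
        D = D ** 2
    np.fill_diagonal(D, np.inf)

    active = np.ones(n, dtype=bool)
    size = np.ones(n, dtype=int)
    node_id = np.arange(n)  # current tree node held at each row
    rep = np.arange(n)  # smallest original entity index in the cluster
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)

    for step in range(n - 1):
        sub = np.where(active)[0]
        block = D[np.ix_(sub, sub)]
        dmin = block.min()
        # deterministic tie-break: smallest (left-rep, right-rep)
        cand = np.argwhere(np.isclose(block, dmin, rtol=0.0, atol=0.0))
        best = None
        for a, b in cand:
            if a >= b:
                continue
            i, j = sub[a], sub[b]
            key = tuple(sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        if rep[j] < rep[i]:
            i, j = j, i

        dij = D[i, j]
        h = np.sqrt(dij) if squared else dij
        merges[step] = (node_id[i], node_id[j])
        heights[step] = h

        ni, nj = size[i], size[j]
        others = sub[(sub != i) & (sub != j)]
        dik, djk = D[i, others], D[j, others]
        if method == "single":
            new = np.minimum(dik, djk)
        elif method == "complete":
            new = np.maximum(dik, djk)
        elif method == "average":
            new = (ni * dik + nj * djk) / (ni + nj)
        elif method == "mcquitty":
            new = 0.5 * (dik + djk)
        elif method == "centroid":
            new = (ni * dik + nj * djk) / (ni + nj) - ni * nj * dij / (ni + nj) ** 2
        else:  # ward
            nk = size[others]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        D[i, others] = D[others, i] = new
        D[i, j] = D[j, i] = np.inf
        active[j] = False
        size[i] = ni + nj
        node_id[i] = n + step
        rep[i] = min(rep[i], rep[j])

    dend = Dendrogram(
        merges=merges,
        heights=heights,
        n_leaves=n,
        method=method,
        entity_ids=entity_ids,
    )
    _order_children(dend)
    return dend


def _order_children(dend: Dendrogram) -> None:
    """Put the child with the smaller minimum original index on the left."""
    for k in range(dend.merges.shape[0]):
        a, b = dend.merges[k]
        if dend.min_leaf(b) < dend.min_leaf(a):
            dend.merges[k] = (b, a)


def cut_dendrogram(
    dend: Dendrogram, k: int | None = None, height: float | None = None
) -> ClusterAssignment:
    """Top-down cluster definition by count k or by cut height.

    With k, the tree is cut at the smallest height yielding k clusters
    (equivalently, the last k-1 merges are undone).  Labels are numbered
    1..k in leaf order.
    """
    n = dend.n_leaves
    if (k is None) == (height is None):
        raise ClusteringError("specify exactly one of k or height")
    if k is not None:
        if not (1 <= k <= n):
            raise ClusteringError(f"k={k} out of range 1..{n}")
        n_apply = n - k
    else:
        if height < 0:
            raise ClusteringError("height must be >= 0")
        n_apply = int(np.sum(dend.heights <= height))

    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n_apply):
        a, b = dend.merges[step]
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node

    labels = np.empty(n, dtype=int)
    label_of_root: dict[int, int] = {}
    next_label = 1
    for leaf in dend.leaf_order:
        r = find(leaf)
        if r not in label_of_root:
            label_of_root[r] = next_label
            next_label += 1
        labels[leaf] = label_of_root[r]
    return ClusterAssignment(labels=labels, k=len(label_of_root), origin="hier_cut")


def select_branch(dend: Dendrogram, node: int) -> ClusterAssignment:
    """Entities under ``node`` become cluster 1; the rest cluster 2."""
    inside = dend.leaves_under(node)
    labels = np.full(dend.n_leaves, 2, dtype=int)
    labels[inside] = 1
    k = 1 if len(inside) == dend.n_leaves else 2
    return ClusterAssignment(labels=labels, k=k, origin="hier_branch")


def auto_color(dend: Dendrogram, depth: int = 1) -> dict[int, str]:
    """Color subtrees rooted ``depth`` levels below the root.

    Every node strictly shallower than ``depth`` keeps the neutral color;
    each subtree whose root sits at exactly ``depth`` (or is a leaf/branch
    that bottoms out earlier) gets a distinct palette color, assigned in
    leaf order so the mapping is deterministic.
    """
    if depth < 1:
        raise ClusteringError("depth must be >= 1")
    colors: dict[int, str] = {}
    subtree_roots: list[int] = []

    def walk(node: int, d: int) -> None:
        if d == depth or dend.children(node) is None:
            subtree_roots.append(node)
            return
        colors[node] = NEUTRAL_COLOR
        a, b = dend.children(node)
        walk(a, d + 1)
        walk(b, d + 1)

    colors[dend.root] = NEUTRAL_COLOR
    if dend.children(dend.root) is None:
        subtree_roots.append(dend.root)
    else:
        a, b = dend.children(dend.root)
        walk(a, 1)
        walk(b, 1)

    subtree_roots.sort(key=dend.min_leaf)
    for idx, r in enumerate(subtree_roots):
        c = PALETTE[idx % len(PALETTE)]
        stack = [r]
        while stack:
            v = stack.pop()
            colors[v] = c
            ch = dend.children(v)
            if ch is not None:
                stack.extend(ch)
    return colors
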