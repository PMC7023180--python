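"""Agglomerative hierarchical clustering via the Lance-Williams recurrence.

The headline linkage is Ward.D: starting from singleton clusters, the pair
of clusters at minimum current inter-cluster distance is merged, and the
distance from the new cluster (i ∪ j) to every other cluster k is updated
with the Lance-Williams coefficients

    alpha_i = (n_i + n_k) / (n_i + n_j + n_k)
    alpha_j = (n_j + n_k) / (n_i + n_j + n_k)
    beta    = -n_k / (n_i + n_j + n_k)
    gamma   = 0

applied to the *plain* input distances (Ward.D convention).  When the input
matrix holds squared Euclidean distances between points, the merge heights
equal twice the increment of the error sum of squares (ESS) incurred by
each merge, which is the quantity Ward's criterion greedily minimises.  A
ward_d2 variant (recurrence on squared distances, rooted heights) and the
classical single / complete / average linkages are provided for sensitivity
analysis.

Merge heights under Ward linkage are monotone non-decreasing (the linkage
is reducible), so the resulting dendrogram has no inversions; this is
asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, color_distance
from .features import ResponsePattern, PatternError

LINKAGES = ("ward_d", "ward_d2", "single", "complete", "average")

_NEWICK_RESERVED = set("();:,[]' \t\n")


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Leaves are node ids ``0..n-1`` (ordered as ``leaf_labels``); internal
    nodes ``n..2n-2`` in merge order.  ``merges[m]`` is
    ``(left_id, right_id, height, merged_size)`` with ``left_id < right_id``.
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    linkage: str = "ward_d"

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ClusteringError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}"
            )
        sizes = {i: 1 for i in range(n)}
        used = set()
        for m, (li, ri, h, sz) in enumerate(self.merges):
            node = n + m
            if li >= node or ri >= node or li == ri:
                raise ClusteringError(f"merge {m} references invalid nodes")
            if li in used or ri in used:
                raise ClusteringError(f"merge {m} reuses a merged node")
            if h < 0:
                raise ClusteringError(f"merge {m} has negative height {h}")
            if sz != sizes[li] + sizes[ri]:
                raise ClusteringError(f"merge {m} size bookkeeping wrong")
            used.update((li, ri))
            sizes[node] = sz

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def leaves_under(self, node: int) -> list[int]:
        """Leaf ids under a node, ascending."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                li, ri, _, _ = self.merges[v - n]
                stack.extend((li, ri))
        return sorted(out)

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.merges), columns=["left", "right", "height", "size"])

    def save_csv(self, path) -> None:
        self.merge_frame().to_csv(path, index=False)


# --- linkage engine -----------------------------------------------------


def _lance_williams_update(
    linkage: str, d_ik: float, d_jk: float, d_ij: float,
    n_i: int, n_j: int, n_k: int,
) -> float:
    if linkage in ("ward_d", "ward_d2"):
        tot = n_i + n_j + n_k
        return ((n_i + n_k) * d_ik + (n_j + n_k) * d_jk - n_k * d_ij) / tot
    if linkage == "single":
        return min(d_ik, d_jk)
    if linkage == "complete":
        return max(d_ik, d_jk)
    if linkage == "average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    raise ClusteringError(f"unknown linkage {linkage!r}")


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "ward_d") -> Dendrogram:
    """Agglomerate a distance matrix into a dendrogram.

    Ties at the minimal merging distance are broken toward the pair with the
    lexicographically smallest (left_id, right_id) — deterministic.  For
    ``ward_d2`` the recurrence runs on squared input distances and heights
    are square-rooted back.
    """
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; expected {LINKAGES}")
    n = d.n
    if n < 2:
        raise ClusteringError("need at least 2 observations")
    square = linkage == "ward_d2"
    # active cluster id -> {other id -> distance}
    dist: dict[int, dict[int, float]] = {
        i: {
            j: (d.values[i, j] ** 2 if square else d.values[i, j])
            for j in range(n) if j != i
        }
        for i in range(n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for m in range(n - 1):
        best: tuple[int, int] | None = None
        best_d = np.inf
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = dist[i][j]
                if dij < best_d:
                    best_d, best = dij, (i, j)
        assert best is not None
        i, j = best
        new = n + m
        height = float(np.sqrt(best_d)) if square else float(best_d)
        merges.append((i, j, height, size[i] + size[j]))
        dist[new] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = _lance_williams_update(
                linkage, dist[i][k], dist[j][k], best_d, size[i], size[j], size[k])
            dist[new][k] = dk
            dist[k][new] = dk
            del dist[k][i], dist[k][j]
        size[new] = size[i] + size[j]
        active.discard(i)
        active.discard(j)
        active.add(new)
        del dist[i], dist[j]
    tree = Dendrogram(leaf_labels=d.labels, merges=tuple(merges), linkage=linkage)
    if linkage in ("ward_d", "ward_d2"):
        h = tree.heights()
        if np.any(np.diff(h) < -1e-9 * max(1.0, float(h.max()))):
            raise ClusteringError("Ward merge heights are not monotone")
    return tree


def cut_tree(tree: Dendrogram, k: int) -> np.ndarray:
    """Partition the leaves into k clusters by removing the k-1 highest merges.

    Returns integer labels 0..k-1 per leaf, numbered by first occurrence in
    leaf order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):  # keep only the n-k lowest merges
        li, ri, _, _ = tree.merges[m]
        node = n + m
        parent[find(li)] = node
        parent[find(ri)] = node
    labels = np.full(n, -1, dtype=int)
    mapping: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in mapping:
            mapping[root] = len(mapping)
        labels[leaf] = mapping[root]
    return labels


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Height of the lowest merge joining each leaf pair (ultrametric)."""
    n = tree.n_leaves
    vals = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m, (li, ri, h, _) in enumerate(tree.merges):
        for a in members[li]:
            for b in members[ri]:
                vals[a, b] = vals[b, a] = h
        members[n + m] = members.pop(li) + members.pop(ri)
    return DistanceMatrix(labels=tree.leaf_labels, values=vals,
                          dialect="cophenetic")


def classify_unknown(
    pattern: ResponsePattern,
    reference: list[ResponsePattern],
    class_labels: list[str],
    dialect: str = "squared",
) -> tuple[str, str, float]:
    """Nearest-reference classification of an unknown response pattern.

    Returns ``(predicted_class, nearest_analyte_id, distance)``; ties are
    broken by reference order.  The caller may threshold on the distance to
    reject out-of-library samples.
    """
    if not reference:
        raise ValueError("reference library is empty")
    if len(reference) != len(class_labels):
        raise ValueError("class_labels must align with reference patterns")
    best_i, best_d = 0, np.inf
    for i, ref in enumerate(reference):
        dd = color_distance(pattern, ref, dialect)
        if dd < best_d:
            best_i, best_d = i, dd
    return class_labels[best_i], reference[best_i].analyte_id, float(best_d)


# --- Newick export ------------------------------------------------------


def _newick_label(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def dendrogram_to_newick(tree: Dendrogram) -> str:
    """Rooted Newick string with branch lengths.

    A node's branch length is the height difference to its parent merge;
    leaves sit at height 0, so the tree is ultrametric.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{_newick_label(tree.leaf_labels[node])}:{parent_h:.10g}"
        li, ri, h, _ = tree.merges[node - n]
        inner = f"({render(li, h)},{render(ri, h)})"
        return f"{inner}:{parent_h - h:.10g}"

    li, ri, h, _ = tree.merges[-1]
    return f"({render(li, h)},{render(ri, h)});"
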