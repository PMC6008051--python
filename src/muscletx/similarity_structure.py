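"""Distance matrices, complete-linkage dendrograms, row-Z-scored matrices.

Tissue profiles (tissue-mean log2(FPKM+1) over expressed transcripts)
are compared by Euclidean distance and clustered by complete-linkage
agglomeration. The agglomeration here is implemented directly rather
than delegated, because the contract requires fully deterministic
output including lexicographic tie-breaking on tissue labels — equal
merge distances are resolved by the smallest (label_a, label_b) pair —
so identical input always yields an identical newick string. Complete
linkage guarantees monotone non-decreasing merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataModelError


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataModelError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise DataModelError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DataModelError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise DataModelError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    ``merges`` lists (left_node, right_node, height) with node ids
    0..n-1 for leaves and n, n+1, ... for internal nodes in merge order.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree."""
        if not self.merges:
            return list(self.labels)
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right, _ = self.merges[node - n]
            return walk(left) + walk(right)

        return [self.labels[i] for i in walk(n + len(self.merges) - 1)]

    def to_newick(self) -> str:
        """Ultrametric newick; each node sits at half its merge height so
        a two-leaf tree merged at height 5 renders as (A:2.5,B:2.5);.
        """
        n = self.n_leaves
        if n == 1:
            return f"{self.labels[0]}:0;"
        node_height = {i: 0.0 for i in range(n)}
        for k, (_, _, h) in enumerate(self.merges):
            node_height[n + k] = h / 2.0

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_h:g}"
            left, right, _ = self.merges[node - n]
            h = node_height[node]
            inner = f"({render(left, h)},{render(right, h)})"
            root = n + len(self.merges) - 1
            return inner if node == root else f"{inner}:{parent_h - h:g}"

        root = n + len(self.merges) - 1
        return render(root, 0.0) + ";"

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k clusters; returns label -> cluster id (0..k-1)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise DataModelError(f"k must be in [1, {n}]")
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for idx, (left, right, _) in enumerate(self.merges[: n - k]):
            node = n + idx
            parent[find(left)] = node
            parent[find(right)] = node
        roots: dict[int, int] = {}
        out = {}
        for i, lab in enumerate(self.labels):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            out[lab] = roots[r]
        return out


def euclidean_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise L2 distances between rows (tissues × features)."""
    if profiles.shape[0] < 2:
        raise DataModelError("need at least 2 tissues")
    if profiles.isna().to_numpy().any():
        raise DataModelError("profiles contain missing values")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(labels=list(profiles.index), values=d)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Deterministic agglomeration; ties broken by lexicographic labels."""
    if linkage != "complete":
        raise DataModelError(f"unsupported linkage {linkage!r}")
    labels = list(dist.labels)
    n = len(labels)
    tree = Dendrogram(labels=labels)
    if n == 1:
        return tree

    # active clusters: node id -> (member leaf indices, smallest member label)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}
    d = dist.values.copy()
    next_node = n
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                da = max(d[i][j] for i in active[a] for j in active[b])
                la, lb = sorted((min_label[a], min_label[b]))
                key = (da, la, lb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _, _), a, b = best
        # children ordered lexicographically by their smallest label
        left, right = (a, b) if min_label[a] <= min_label[b] else (b, a)
        tree.merges.append((left, right, float(height)))
        active[next_node] = active.pop(a) + active.pop(b)
        min_label[next_node] = min(min_label[a], min_label[b])
        next_node += 1
    return tree


def cophenetic_matrix(tree: Dendrogram) -> pd.DataFrame:
    """Cophenetic distances (merge height joining each leaf pair)."""
    n = tree.n_leaves
    members = {i: [i] for i in range(n)}
    out = np.zeros((n, n))
    for k, (left, right, h) in enumerate(tree.merges):
        for i in members[left]:
            for j in members[right]:
                out[i, j] = out[j, i] = h
        members[n + k] = members[left] + members[right]
    return pd.DataFrame(out, index=tree.labels, columns=tree.labels)


def subset_by_family(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_prefix_or_list: str | list[str],
) -> pd.DataFrame:
    """Restrict expression rows to a gene family (prefix or explicit list)."""
    symbols = annotation.loc[expr.index, "gene_symbol"].astype(str)
    if isinstance(gene_prefix_or_list, str):
        mask = symbols.str.upper().str.startswith(gene_prefix_or_list.upper())
    else:
        wanted = {g.upper() for g in gene_prefix_or_list}
        mask = symbols.str.upper().isin(wanted)
    sub = expr.loc[mask.to_numpy()]
    if sub.empty:
        raise DataModelError(f"no transcripts match family {gene_prefix_or_list!r}")
    return sub


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row Z-scores with sample (n−1) SD; constant rows → zeros, flagged."""
    if matrix.shape[1] < 2:
        raise DataModelError("need at least 2 columns to z-score rows")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    sd[constant, :] = 1.0
    z = (vals - mean) / sd
    z[constant, :] = 0.0
    flagged = [matrix.index[i] for i in np.flatnonzero(constant)]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged
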