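"""Pearson-correlation average-linkage clustering and heatmap export.

Unsupervised structure recovery over expression profiles: distance is
1 - Pearson correlation, agglomeration is UPGMA (size-weighted average
linkage) with deterministic smallest-index tie-breaking, and a k-group
partition is obtained by undoing the last k-1 merges. A doubly-reordered
matrix plus Newick trees can be exported for heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix


@dataclass
class Dendrogram:
    """Agglomeration record: (node_a, node_b, height, new_node_id) merges.

    Leaves are numbered 0..n-1 (ids in ``leaf_ids``); internal nodes n..2n-2
    in merge order. Average linkage cannot invert, so heights are
    nondecreasing along any root path.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf positions under the merge tree."""
        children: dict[int, tuple[int, int]] = {
            new: (a, b) for a, b, _, new in self.merges}
        root = self.merges[-1][3] if self.merges else 0

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        return walk(root)

    def to_newick(self) -> str:
        """Newick with branch lengths = merge-height differences."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        children: dict[int, tuple[int, int]] = {}
        for a, b, h, new in self.merges:
            heights[new] = h
            children[new] = (a, b)
        root = self.merges[-1][3] if self.merges else 0

        def render(node: int, parent_h: float) -> str:
            length = parent_h - heights[node]
            if node < self.n_leaves:
                return f"{self.leaf_ids[node]}:{length:g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{length:g}"

        if not self.merges:
            return f"{self.leaf_ids[0]};"
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def correlation_distance(matrix: ExpressionMatrix, axis: str = "samples") -> np.ndarray:
    """Pairwise d = 1 - Pearson r between profiles; range [0, 2].

    axis="samples" compares columns (profiles over genes); axis="genes"
    compares rows. Constant profiles have undefined correlation and are an
    error.
    """
    if axis == "samples":
        profiles = matrix.values.T
        names = matrix.sample_ids
    elif axis == "genes":
        profiles = matrix.values
        names = matrix.gene_symbols
    else:
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 observations per profile")
    sd = profiles.std(axis=1)
    flat = [names[i] for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"constant profile(s), Pearson undefined: {flat[:5]}")
    r = np.corrcoef(profiles)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def average_linkage(dist: np.ndarray, leaf_ids: list[str] | None = None) -> Dendrogram:
    """UPGMA agglomeration with smallest-(i, j)-index tie-breaking.

    Repeatedly merges the closest pair of clusters; the merged cluster's
    distance to any other is the size-weighted mean of its members'
    distances (i.e. the mean pairwise leaf distance).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    leaf_ids = [str(i) for i in range(n)] if leaf_ids is None else list(leaf_ids)

    D = dist.astype(float).copy()
    active: list[int] = list(range(n))        # positions into D
    node_of = {i: i for i in range(n)}        # D position -> tree node id
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    INF = np.inf
    work = D.copy()
    np.fill_diagonal(work, INF)
    alive = np.ones(n, dtype=bool)

    for _ in range(n - 1):
        sub = np.where(alive[:, None] & alive[None, :], work, INF)
        # smallest (i, j) index pair among minima: flat argmin scans row-major
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        if i > j:
            i, j = j, i
        h = work[i, j]
        ni, nj = sizes[i], sizes[j]
        # size-weighted average to every other cluster
        new_row = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i] = new_row
        work[:, i] = new_row
        work[i, i] = INF
        alive[j] = False
        merges.append((node_of[i], node_of[j], float(h), next_id))
        node_of[i] = next_id
        sizes[i] = ni + nj
        next_id += 1
    return Dendrogram(leaf_ids=leaf_ids, merges=merges)


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns integer labels 1..k, numbered by order of first appearance
    over the leaves.
    """
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _, new in dend.merges[: n - k]:
        parent[find(a)] = parent[find(b)] = new
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[leaf] = seen[root]
    return labels


def export_heatmap_order(matrix: ExpressionMatrix, sample_dend: Dendrogram,
                         gene_dend: Dendrogram, prefix) -> dict[str, str]:
    """Write the doubly-reordered matrix (TSV) and both trees (Newick).

    Returns the paths written, keyed "matrix", "sample_tree", "gene_tree".
    """
    if sample_dend.leaf_ids != list(matrix.sample_ids):
        raise ValueError("sample dendrogram leaves do not match matrix samples")
    if gene_dend.leaf_ids != list(matrix.gene_symbols):
        raise ValueError("gene dendrogram leaves do not match matrix genes")
    s_order = sample_dend.leaf_order()
    g_order = gene_dend.leaf_order()
    reordered = matrix.copy_with(
        values=matrix.values[np.ix_(g_order, s_order)],
        gene_symbols=[matrix.gene_symbols[i] for i in g_order],
        sample_ids=[matrix.sample_ids[i] for i in s_order])
    from .data import write_expression_matrix

    prefix = str(prefix)
    paths = {"matrix": prefix + ".matrix.tsv",
             "sample_tree": prefix + ".samples.nwk",
             "gene_tree": prefix + ".genes.nwk"}
    write_expression_matrix(reordered, paths["matrix"], format="tsv")
    with open(paths["sample_tree"], "w") as fh:
        fh.write(sample_dend.to_newick() + "\n")
    with open(paths["gene_tree"], "w") as fh:
        fh.write(gene_dend.to_newick() + "\n")
    return paths
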