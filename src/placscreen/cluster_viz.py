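"""2D hierarchical clustering of the gene x sample log2-FC matrix.

Similarity is centered Pearson correlation (distance ``1 - r``, range
[0, 2]); linkage is UPGMA (average linkage): at every step the pair of
clusters with the minimal size-weighted mean inter-cluster distance is
merged.  Ties are broken deterministically by the lexicographically
smallest member labels, and leaf ordering places the subtree containing
the smallest label first at every internal node, so the output is a pure
function of the input matrix.

The heatmap "export" is text only: the matrix reordered by both leaf
orders with median-centered gene rows, the two orders, the clinical
annotation row, and a metadata note fixing the red = up / green = down
sign convention.  Rendering an image is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "HeatmapExport",
    "centered_correlation_distance",
    "average_linkage",
    "build_heatmap",
]


@dataclass
class Dendrogram:
    """Merge list + deterministic leaf order for one clustering axis.

    Leaves are numbered ``0..n-1`` (in ``labels`` order); each merge
    ``(a, b, height, new_id)`` creates internal node ``new_id`` starting
    at ``n``.  Heights are non-decreasing (UPGMA monotonicity).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    axis: str = "genes"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices; smallest-label subtree first."""
        n = self.n_leaves
        if not self.merges:
            return list(range(n))
        children = {m[3]: (m[0], m[1]) for m in self.merges}
        smallest: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for a, b, _, new in self.merges:
            smallest[new] = min(smallest[a], smallest[b])

        order: list[int] = []

        def walk(node: int) -> None:
            if node < n:
                order.append(node)
                return
            a, b = children[node]
            first, second = (a, b) if smallest[a] <= smallest[b] else (b, a)
            walk(first)
            walk(second)

        walk(self.merges[-1][3])
        return order

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order()]


def centered_correlation_distance(
    matrix: pd.DataFrame, axis: str = "rows", centered: bool = True
) -> pd.DataFrame:
    """Pairwise correlation distance ``d = 1 - r`` between rows or columns.

    ``centered=True`` is ordinary Pearson correlation (vectors are mean
    centered); ``centered=False`` is the uncentered variant (cosine
    similarity of the raw vectors).  A zero-variance vector has no
    defined correlation and is reported by id.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix.to_numpy(dtype=float)
    ids = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "columns":
        data = data.T
    if len(ids) < 2:
        raise ValueError("need at least two vectors to cluster")
    if centered:
        data = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((data**2).sum(axis=1))
    zero = [ids[i] for i in np.nonzero(norms == 0)[0]]
    if zero:
        raise ValueError(f"zero-variance vectors on axis {axis!r}: {zero}")
    unit = data / norms[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def average_linkage(dist: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    New cluster distances are size-weighted averages (Lance-Williams for
    UPGMA), which equals the mean over all cross-pair leaf distances.
    Ties on the minimal distance are resolved toward the candidate pair
    whose sorted pair of smallest member labels is lexicographically
    least.
    """
    d = dist.to_numpy(dtype=float).copy()
    labels = [str(x) for x in dist.index]
    n = len(labels)
    if list(dist.columns) != list(dist.index):
        raise ValueError("distance matrix index and columns differ")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    active: dict[int, int] = {i: 1 for i in range(n)}  # node -> size
    smallest: dict[int, str] = {i: labels[i] for i in range(n)}
    index_of: dict[int, int] = {i: i for i in range(n)}  # node -> row in d
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    nodes = list(range(n))
    for _ in range(n - 1):
        best = None
        for ii, u in enumerate(nodes):
            for v in nodes[ii + 1:]:
                duv = d[index_of[u], index_of[v]]
                key_labels = tuple(sorted((smallest[u], smallest[v])))
                cand = (duv, key_labels, u, v)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        height, _, u, v = best
        iu, iv = index_of[u], index_of[v]
        su, sv = active[u], active[v]
        # Lance-Williams update for UPGMA into row iu
        for w in nodes:
            if w in (u, v):
                continue
            iw = index_of[w]
            d[iu, iw] = d[iw, iu] = (su * d[iu, iw] + sv * d[iv, iw]) / (su + sv)
        merges.append((u, v, float(height), next_id))
        active[next_id] = su + sv
        smallest[next_id] = min(smallest[u], smallest[v])
        index_of[next_id] = iu
        nodes = [w for w in nodes if w not in (u, v)] + [next_id]
        del active[u], active[v]
        next_id += 1
    return Dendrogram(labels=labels, merges=merges, axis=axis)


@dataclass
class HeatmapExport:
    """Clustered-matrix export: reordered values + orders + annotations."""

    matrix: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    annotations: pd.Series | None = None
    metadata: dict[str, str] = field(default_factory=dict)


def build_heatmap(
    matrix: pd.DataFrame,
    gene_tree: Dendrogram,
    sample_tree: Dendrogram | None = None,
    annotations: Mapping[str, str] | pd.Series | None = None,
    center: str = "median",
) -> HeatmapExport:
    """Reorder the log2-FC matrix by the dendrogram leaf orders.

    Gene rows are median-centered (``center="none"`` disables this);
    samples keep their input order when ``sample_tree`` is None, which
    reproduces the genes-only presentation with samples grouped by
    clinical status.  The sign convention (red = up, green = down) is
    recorded in the metadata.
    """
    row_order = gene_tree.ordered_labels()
    if set(row_order) != set(matrix.index):
        raise ValueError("gene tree leaves do not match matrix rows")
    if sample_tree is not None:
        col_order = sample_tree.ordered_labels()
        if set(col_order) != set(matrix.columns):
            raise ValueError("sample tree leaves do not match matrix columns")
    else:
        col_order = list(matrix.columns)
    out = matrix.loc[row_order, col_order].astype(float)
    if center == "median":
        out = out.sub(out.median(axis=1), axis=0)
    elif center != "none":
        raise ValueError("center must be 'median' or 'none'")
    ann = None
    if annotations is not None:
        ann = pd.Series(dict(annotations)).reindex(col_order)
    return HeatmapExport(
        matrix=out,
        row_order=row_order,
        col_order=col_order,
        annotations=ann,
        metadata={
            "values": f"{center}-centered log2 fold change",
            "color_convention": "red=up-regulated, green=down-regulated",
        },
    )
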