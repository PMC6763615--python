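"""Cohort preprocessing, significance filtering and Ward clustering.

The cohort analysis follows the classical heatmap workflow for antibody
array data: log2-transform the density matrix, center each sample at its
median (removing exposure and loading differences), z-score each analyte
across samples, filter analytes that differ between the two diagnostic
groups (Welch t-test, unadjusted p < alpha — the field's customary,
liberal filter), then cluster both axes hierarchically with Ward linkage
over correlation distances. "Supervised" means the group labels drive
the filter; the clustering itself is unsupervised on the filtered
matrix.

The agglomeration is implemented natively with a documented,
platform-deterministic tie rule (merge the lexicographically smallest
cluster-id pair among minimal-distance pairs) via the Lance-Williams
update for Ward linkage applied to squared correlation distances; merge
heights are on the distance (not squared) scale, as in R's ``ward.D2``.
Values are clipped to [-3, 3] only at heatmap export, never before
clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortMatrix
from .errors import ClusterError, ConfigError, DataError, DistanceError

__all__ = [
    "Dendrogram",
    "ClusterResult",
    "preprocess_matrix",
    "filter_significant",
    "correlation_distance",
    "hierarchical_cluster",
    "cut_dendrogram",
    "cluster_cohort",
    "heatmap_export",
]


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_matrix(
    matrix: CohortMatrix | pd.DataFrame,
    pseudocount: float = 1.0,
    center_samples: bool = True,
    scale_analytes: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """log2(value + pseudocount), sample median centering, analyte z-score.

    Returns (transformed samples x analytes frame, dropped analytes).
    Analytes constant across samples have no scale and are dropped with
    a warning (they carry no clustering information). The z-score uses
    the sample standard deviation (ddof=1), matching R's ``scale()``.
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else matrix
    if (values.to_numpy() < 0).any():
        raise DataError("cohort matrix contains negative densities")
    logged = np.log2(values + pseudocount)
    if center_samples:
        logged = logged.sub(logged.median(axis=1), axis=0)
    dropped: list[str] = []
    if scale_analytes:
        sd = logged.std(axis=0, ddof=1)
        # relative tolerance: summation round-off makes "constant" columns
        # come out at sd ~ 1e-16, not exactly 0
        tol = 1e-12 * logged.abs().max(axis=0).clip(lower=1.0)
        dropped = sd.index[(sd <= tol) | sd.isna()].tolist()
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} zero-variance analytes: {dropped}", stacklevel=2
            )
        kept = logged.drop(columns=dropped)
        logged = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return logged, dropped


def filter_significant(
    matrix: CohortMatrix,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[CohortMatrix, pd.Series]:
    """Keep analytes differing between the two groups (Welch test, p < alpha).

    Exactly two diagnostic groups are supported; each needs at least two
    samples. Tests run on log2(value + pseudocount); p-values are
    reported unadjusted. ``alpha >= 1`` keeps every testable analyte.
    """
    groups = matrix.groups
    labels = groups.unique().tolist()
    if len(labels) != 2:
        raise DataError(
            f"significance filter requires exactly 2 groups, got {len(labels)}: {labels}"
        )
    for g in labels:
        if int((groups == g).sum()) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
    logged = np.log2(matrix.values + pseudocount)
    a = logged[groups == labels[0]]
    b = logged[groups == labels[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
    pvals = pd.Series(res.pvalue, index=matrix.values.columns, name="p_value")
    # identical constant groups give 0/0 -> NaN; no evidence of difference
    pvals = pvals.fillna(1.0)
    keep = pvals.index[(pvals < alpha) | (alpha >= 1.0)].tolist()
    return matrix.subset_analytes(keep), pvals


# ---------------------------------------------------------------------------
# Distances and agglomeration


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]; undefined for constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DistanceError("correlation distance needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DistanceError("correlation distance undefined for zero-variance vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def _correlation_distance_matrix(rows: np.ndarray, labels: list[str]) -> np.ndarray:
    sds = rows.std(axis=1)
    tol = 1e-12 * np.maximum(1.0, np.abs(rows).max(axis=1))
    constant = [labels[i] for i in np.flatnonzero(sds <= tol)]
    if constant:
        raise ClusterError(f"constant vectors cannot be clustered: {constant}")
    corr = np.corrcoef(rows)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Merge tree in scipy linkage convention with leaf labels.

    ``linkage`` row t merges cluster ids Z[t,0] and Z[t,1] (original
    leaves are 0..n-1, the merge at row t creates id n+t) at height
    Z[t,2] into a cluster of Z[t,3] leaves.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the merge tree."""
        n = self.n_leaves

        def descend(node: int) -> list[int]:
            if node < n:
                return [node]
            row = self.linkage[node - n]
            return descend(int(row[0])) + descend(int(row[1]))

        return [self.labels[i] for i in descend(2 * n - 2)] if n > 1 else list(self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for t, row in enumerate(self.linkage):
            heights[n + t] = float(row[2])

        def node_str(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < n:
                return f"{self.labels[node]}:{length:.6g}"
            row = self.linkage[node - n]
            left = node_str(int(row[0]), heights[node])
            right = node_str(int(row[1]), heights[node])
            return f"({left},{right}):{length:.6g}"

        root = 2 * n - 2
        if n == 1:
            return f"{self.labels[0]};"
        row = self.linkage[-1]
        left = node_str(int(row[0]), heights[root])
        right = node_str(int(row[1]), heights[root])
        return f"({left},{right});"

    def to_nested_json(self) -> str:
        n = self.n_leaves

        def node(i: int) -> dict:
            if i < n:
                return {"leaf": self.labels[i], "height": 0.0}
            row = self.linkage[i - n]
            return {
                "height": float(row[2]),
                "children": [node(int(row[0])), node(int(row[1]))],
            }

        return json.dumps(node(2 * n - 2) if n > 1 else node(0), indent=2)


def ward_linkage(distance_matrix: np.ndarray) -> np.ndarray:
    """Ward agglomeration over an arbitrary dissimilarity matrix.

    Lance-Williams recursion on squared dissimilarities (the ``ward.D2``
    convention: singleton merge height equals the input dissimilarity).
    Ties are broken by the lexicographically smallest (id_i, id_j) pair,
    which makes merge sequences platform-deterministic.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ClusterError("need at least 2 items to cluster")
    d2: dict[tuple[int, int], float] = {
        (i, j): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active: list[int] = list(range(n))
    Z = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (i, j) if i < j else (j, i)
                cand = (d2[key], key[0], key[1])
                if best is None or cand < best:
                    best = cand
        dist2, i, j = best
        height = float(np.sqrt(max(dist2, 0.0)))
        si, sj = sizes[i], sizes[j]
        Z[step] = (i, j, height, si + sj)
        k = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            sm = sizes[m]
            dim = d2[(min(i, m), max(i, m))]
            djm = d2[(min(j, m), max(j, m))]
            d2[(min(k, m), max(k, m))] = (
                (si + sm) * dim + (sj + sm) * djm - sm * dist2
            ) / (si + sj + sm)
        active = [m for m in active if m not in (i, j)] + [k]
        sizes[k] = si + sj
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-9 * max(1.0, heights.max())):
        raise ClusterError("Ward merge heights are not monotone; numerical failure")
    return Z


def hierarchical_cluster(
    matrix: pd.DataFrame | CohortMatrix,
    axis: str = "analytes",
) -> Dendrogram:
    """Ward / correlation-distance dendrogram over one axis of the matrix.

    ``matrix`` is samples x analytes; ``axis`` picks which becomes the
    clustered items (rows of the distance computation). Constant vectors
    make the correlation undefined and are rejected by name.
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else matrix
    if axis == "analytes":
        items = values.T
    elif axis == "samples":
        items = values
    else:
        raise ConfigError(f"axis must be 'analytes' or 'samples', got {axis!r}")
    labels = [str(x) for x in items.index]
    rows = items.to_numpy(dtype=float)
    if rows.shape[0] < 2:
        raise ClusterError(f"need at least 2 {axis} to cluster, got {rows.shape[0]}")
    D = _correlation_distance_matrix(rows, labels)
    Z = ward_linkage(D)
    return Dendrogram(linkage=Z, labels=labels)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly k clusters by removing the k-1 tallest merges.

    Because Ward heights are monotone along the merge sequence, this is
    the partition after the first n-k merges. Cluster ids 0..k-1 are
    assigned in order of each cluster's lexicographically smallest
    member label, so the assignment is stable under leaf reordering.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_root = {i: i for i in range(n)}
    for t in range(n - k):
        a, b, _, _ = dendrogram.linkage[t]
        ra, rb = find(node_root[int(a)]), find(node_root[int(b)])
        parent[rb] = ra
        members[ra].extend(members.pop(rb))
        node_root[n + t] = ra
    clusters = sorted(members.values(), key=lambda m: min(dendrogram.labels[i] for i in m))
    assignment: dict[str, int] = {}
    for cid, m in enumerate(clusters):
        for i in m:
            assignment[dendrogram.labels[i]] = cid
    return assignment


# ---------------------------------------------------------------------------
# Pipeline and export


@dataclass
class ClusterResult:
    """Filtered, scaled and clustered cohort ready for heatmap display."""

    analytes: list[str]
    p_values: pd.Series
    scaled: pd.DataFrame  # analytes x samples, rows mean 0 / SD 1
    row_dendrogram: Dendrogram  # analytes
    col_dendrogram: Dendrogram  # samples
    groups: pd.Series
    alpha: float
    linkage: str = "ward"
    distance: str = "correlation"


def cluster_cohort(
    matrix: CohortMatrix,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    require_filtered: bool = False,
) -> ClusterResult:
    """Filter -> preprocess -> cluster both axes.

    When the significance filter keeps fewer than 2 analytes and
    ``require_filtered`` is False, the full matrix is clustered instead
    (the filter is reported but not applied); with ``require_filtered``
    True this raises.
    """
    filtered, pvals = filter_significant(matrix, alpha=alpha, pseudocount=pseudocount)
    if len(filtered.analytes) < 2:
        if require_filtered:
            raise ClusterError(
                f"only {len(filtered.analytes)} analytes pass the p<{alpha} filter"
            )
        filtered = matrix
    scaled_sxa, _ = preprocess_matrix(filtered, pseudocount=pseudocount)
    if scaled_sxa.shape[1] < 2:
        raise ClusterError("fewer than 2 analytes with variance; cannot cluster")
    row_dend = hierarchical_cluster(scaled_sxa, axis="analytes")
    col_dend = hierarchical_cluster(scaled_sxa, axis="samples")
    return ClusterResult(
        analytes=list(scaled_sxa.columns),
        p_values=pvals,
        scaled=scaled_sxa.T,
        row_dendrogram=row_dend,
        col_dendrogram=col_dend,
        groups=matrix.groups,
        alpha=alpha,
    )


def heatmap_export(result: ClusterResult, outdir=None, render: bool = False) -> dict:
    """Clip the scaled matrix to [-3, 3] and order it by the dendrograms.

    Returns a bundle with the display matrix (analytes x samples, rows
    and columns in dendrogram leaf order), the orders, per-sample group
    annotations and Newick trees. When ``outdir`` is given, writes
    heatmap.csv, ordering.json, rows.nwk, cols.nwk and (optionally) a
    rendered heatmap.png.
    """
    row_order = result.row_dendrogram.leaf_order()
    col_order = result.col_dendrogram.leaf_order()
    display = result.scaled.loc[row_order, col_order].clip(-3.0, 3.0)
    groups = result.groups.loc[col_order]
    palette = {g: f"C{i}" for i, g in enumerate(pd.unique(groups))}
    bundle = {
        "matrix": display,
        "row_order": row_order,
        "col_order": col_order,
        "group_annotations": {s: str(g) for s, g in groups.items()},
        "group_colors": {s: palette[g] for s, g in groups.items()},
        "row_newick": result.row_dendrogram.to_newick(),
        "col_newick": result.col_dendrogram.to_newick(),
        "value_range": [-3.0, 3.0],
    }
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        display.to_csv(out / "heatmap.csv")
        (out / "ordering.json").write_text(
            json.dumps(
                {
                    "row_order": row_order,
                    "col_order": col_order,
                    "group_annotations": bundle["group_annotations"],
                    "value_range": bundle["value_range"],
                },
                indent=2,
            )
        )
        (out / "rows.nwk").write_text(bundle["row_newick"] + "\n")
        (out / "cols.nwk").write_text(bundle["col_newick"] + "\n")
        if render:
            _render_heatmap_png(display, groups, out / "heatmap.png")
    return bundle


def _render_heatmap_png(display: pd.DataFrame, groups: pd.Series, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.4 * display.shape[1]), max(3.0, 0.18 * display.shape[0]))
    )
    im = ax.imshow(display.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xticks(range(display.shape[1]))
    ax.set_xticklabels([f"{c}\n{groups[c]}" for c in display.columns], fontsize=6, rotation=90)
    ax.set_yticks(range(display.shape[0]))
    ax.set_yticklabels(display.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score (clipped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
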