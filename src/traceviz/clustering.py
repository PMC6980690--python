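"""Hierarchical clustering of traces with cluster-validation indices.

Traces sharing a common time grid are stacked into an objects x
timepoints matrix, pairwise distances are computed (Euclidean or classic
dynamic time warping) and clustered agglomeratively with the Ward.D2
criterion (minimum increase of within-cluster variance, applied to the
unsquared distance matrix).  Candidate cluster counts k are scored by
three cluster-validation indices — Calinski–Harabasz, mean silhouette
width and the Dunn index — all oriented so that higher is better; the
argmax over k guides the choice of cluster number, with the caveat that
a CVI is a summary statistic of the data, not of the underlying biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .dataio import TraceSet

__all__ = [
    "ClusterResult",
    "trace_matrix",
    "euclidean_distance_matrix",
    "dtw_distance",
    "dtw_distance_matrix",
    "hierarchical_cluster",
    "calinski_harabasz",
    "silhouette_index",
    "dunn_index",
    "cvi_scan",
    "render_cluster_facets",
]

CVI_NAMES = ("calinski_harabasz", "silhouette", "dunn")
DISTANCES = ("euclidean", "dtw")


@dataclass
class ClusterResult:
    """Assignments at the selected k plus the CVI table over the k scan."""

    distance: str
    linkage: str
    k: int
    assignments: dict[str, int]
    cvi_table: pd.DataFrame = dc_field(repr=False)  # columns: index, k, value
    best_k: dict[str, int] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# matrix assembly


def trace_matrix(ts: TraceSet) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack traces into an (objects x timepoints) matrix.

    Only time points at which *every* object has a non-missing value are
    kept (a warning reports any dropped times).  Returns
    ``(matrix, object_labels, times)``; object labels are prefixed by the
    condition when ids collide across conditions.
    """
    df = ts.data.copy()
    if df["object_id"].groupby(df["object_id"]).size().size != len(
        df.groupby(["condition_id", "object_id"]).size()
    ):
        df["object_id"] = df["condition_id"] + ":" + df["object_id"]
    wide = df.pivot_table(
        index="object_id", columns="time", values="value", aggfunc="first",
        dropna=False,
    )
    order = list(dict.fromkeys(df["object_id"]))
    wide = wide.reindex(order)
    complete = wide.notna().all(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} time point(s) not shared by all objects",
            stacklevel=2,
        )
    wide = wide.loc[:, complete]
    if wide.shape[1] == 0:
        raise ValueError(
            "objects share no common time points; resample the data onto a "
            "common grid before clustering"
        )
    return (
        wide.to_numpy(dtype=float),
        list(wide.index),
        wide.columns.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# distances


def euclidean_distance_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows of M."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.isnan(M).any():
        raise ValueError("distance computation requires complete data")
    return squareform(pdist(M, metric="euclidean"))


def dtw_distance(a, b) -> float:
    """Classic dynamic time warping distance between two series.

    Local cost |a_i - b_j|, symmetric match/insert/delete steps, no window
    constraint and no normalization:
    ``D(i,j) = cost(i,j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("series must not contain missing values")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[n, m])


def dtw_distance_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise DTW distances between rows of M."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    m = M.shape[0]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = dtw_distance(M[i], M[j])
    return D


def _as_condensed(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        return D
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return squareform(D, checks=False)


# ---------------------------------------------------------------------------
# clustering


def hierarchical_cluster(D: np.ndarray, k: int) -> np.ndarray:
    """Cut a Ward.D2 agglomerative tree at k clusters.

    Returns contiguous 1-based cluster indices per row of D, numbered by
    first appearance.  Deterministic for a given distance matrix.
    """
    condensed = _as_condensed(D)
    m = squareform(condensed, checks=False).shape[0]
    if not 2 <= k <= m - 1:
        raise ValueError(f"k must lie in [2, {m - 1}] for {m} objects; got {k}")
    Z = linkage(condensed, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance so indices are stable and contiguous
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[i] = remap[c]
    return out


def ward_linkage_heights(D: np.ndarray) -> np.ndarray:
    """Merge heights of the Ward.D2 tree (nondecreasing)."""
    return linkage(_as_condensed(D), method="ward")[:, 2]


# ---------------------------------------------------------------------------
# cluster validation indices (all oriented higher = better)


def _check_partition(n: int, labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    if labels.size != n:
        raise ValueError("one label per object is required")
    k = np.unique(labels).size
    if k < 2 or k >= n:
        raise ValueError(f"index undefined for k={k} with {n} objects")
    return k


def calinski_harabasz(M: np.ndarray, assignments) -> float:
    """Calinski–Harabasz index: [B/(k-1)] / [W/(m-k)].

    B and W are the between- and within-cluster sums of squared distances
    to the (grand/cluster) centroids.  Returns +inf when W = 0 with B > 0,
    and 0 when all points coincide (B = 0).
    """
    M = np.asarray(M, dtype=float)
    labels = np.asarray(assignments)
    m = M.shape[0]
    k = _check_partition(m, labels)
    grand = M.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in np.unique(labels):
        X = M[labels == c]
        cen = X.mean(axis=0)
        B += X.shape[0] * float(np.sum((cen - grand) ** 2))
        W += float(np.sum((X - cen) ** 2))
    if W == 0.0:
        return float("inf") if B > 0 else 0.0
    return (B / (k - 1)) / (W / (m - k))


def silhouette_index(D: np.ndarray, assignments) -> float:
    """Mean silhouette width computed from the distance matrix."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(assignments)
    m = D.shape[0]
    _check_partition(m, labels)
    uniq = np.unique(labels)
    s = np.zeros(m)
    for i in range(m):
        own = labels[i]
        same = (labels == own) & (np.arange(m) != i)
        if not same.any():
            s[i] = 0.0  # singleton cluster convention
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def dunn_index(D: np.ndarray, assignments) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(assignments)
    m = D.shape[0]
    _check_partition(m, labels)
    uniq = np.unique(labels)
    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if idx.size > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for ai in range(len(uniq)):
        for bi in range(ai + 1, len(uniq)):
            ia = np.flatnonzero(labels == uniq[ai])
            ib = np.flatnonzero(labels == uniq[bi])
            min_sep = min(min_sep, float(D[np.ix_(ia, ib)].min()))
    if max_diam == 0.0:
        return float("inf") if min_sep > 0 else 0.0
    return min_sep / max_diam


_CVI_FROM_MATRIX = {"calinski_harabasz": True, "silhouette": False, "dunn": False}


def cvi_scan(
    M: np.ndarray,
    distance: str = "euclidean",
    linkage_method: str = "ward.d2",
    k_range=range(2, 7),
    indices=CVI_NAMES,
    object_ids: list[str] | None = None,
) -> ClusterResult:
    """Score a range of cluster counts with the validation indices.

    Clusters the rows of M for each k in ``k_range``, evaluates every
    requested index and reports the full table plus the argmax-k per index
    (ties broken toward the smallest k).  The returned assignments are the
    cut at the Calinski–Harabasz argmax (or the first requested index).
    """
    if linkage_method.lower() not in ("ward.d2", "ward"):
        raise ValueError("only the ward.d2 linkage is supported")
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    bad = [k for k in ks if not 2 <= k <= m - 1]
    if bad:
        raise ValueError(f"k values out of range [2, {m - 1}]: {bad}")
    for name in indices:
        if name not in CVI_NAMES:
            raise ValueError(f"unknown CVI {name!r}; choose from {CVI_NAMES}")

    D = euclidean_distance_matrix(M) if distance == "euclidean" else dtw_distance_matrix(M)

    rows = []
    cuts: dict[int, np.ndarray] = {}
    for k in ks:
        labels = hierarchical_cluster(D, k)
        cuts[k] = labels
        for name in indices:
            if _CVI_FROM_MATRIX[name]:
                val = calinski_harabasz(M, labels)
            elif name == "silhouette":
                val = silhouette_index(D, labels)
            else:
                val = dunn_index(D, labels)
            rows.append((name, k, val))
    table = pd.DataFrame(rows, columns=["index", "k", "value"])

    best_k: dict[str, int] = {}
    for name in indices:
        sub = table[table["index"] == name].sort_values("k")
        # ties toward smallest k: idxmax returns the first maximal row
        best_k[name] = int(sub.loc[sub["value"].idxmax(), "k"])

    primary = "calinski_harabasz" if "calinski_harabasz" in indices else indices[0]
    chosen = best_k[primary]
    labels = cuts[chosen]
    ids = object_ids if object_ids is not None else [str(i) for i in range(m)]
    if len(ids) != m:
        raise ValueError("object_ids length must match the matrix")
    return ClusterResult(
        distance=distance,
        linkage="ward.d2",
        k=chosen,
        assignments={o: int(c) for o, c in zip(ids, labels)},
        cvi_table=table,
        best_k=best_k,
    )


# ---------------------------------------------------------------------------
# display


def render_cluster_facets(ts: TraceSet, result: ClusterResult, spec=None):
    """One panel per cluster; traces colored by condition.

    Coloring by condition makes the cross-condition composition of each
    cluster visible (e.g. which signaling dynamics dominate a cluster).
    """
    from .palettes import DEFAULT_PALETTE, assign_colors, builtin_palette
    from .plotting import DPI, PlotSpec, small_multiples_grid
    import matplotlib.pyplot as plt

    spec = spec or PlotSpec()
    df = ts.data.copy()
    if set(df["object_id"]) - set(result.assignments):
        # trace_matrix may have prefixed colliding ids with the condition
        df["object_id"] = df["condition_id"] + ":" + df["object_id"]
    missing = set(df["object_id"]) - set(result.assignments)
    if missing:
        raise ValueError(f"objects without a cluster assignment: {sorted(missing)}")

    clusters = sorted(set(result.assignments.values()))
    rows, cols = small_multiples_grid(len(clusters))
    fig, axes = plt.subplots(
        rows, cols, figsize=spec.figsize(), dpi=DPI,
        sharex=True, sharey=True, squeeze=False,
    )
    flat = axes.ravel()
    conditions = list(dict.fromkeys(df["condition_id"]))
    pal = spec.palette if spec.palette is not None else builtin_palette(DEFAULT_PALETTE)
    if not hasattr(pal, "colors"):
        pal = builtin_palette(DEFAULT_PALETTE)
    cond_colors = dict(zip(conditions, assign_colors(len(conditions), pal)))

    for ax, c in zip(flat, clusters):
        members = [o for o, cc in result.assignments.items() if cc == c]
        for obj in members:
            g = df[df["object_id"] == obj].sort_values("time")
            ax.plot(
                g["time"],
                g["value"],
                color=cond_colors[g["condition_id"].iloc[0]],
                alpha=spec.data_alpha,
                linewidth=spec.data_linewidth,
                gid="trace",
            )
        ax.set_title(f"Cluster {c} (n={len(members)})", fontsize=9)
    for ax in flat[len(clusters):]:
        fig.delaxes(ax)
    fig.supxlabel(spec.x_label)
    fig.supylabel(spec.y_label)
    return fig
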