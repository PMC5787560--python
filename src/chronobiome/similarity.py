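"""Temporal-shape distances between taxa and hierarchical clustering.

Euclidean distance penalises phase shifts: two taxa tracing the same curve
one step apart score as dissimilar.  Dynamic time warping (DTW) aligns the
two series by dynamic programming before scoring, so phase-displaced shapes
match.  A Sakoe-Chiba band of half-width ``band`` restricts the warping path
to a diagonal corridor, which both limits pathological warps and reduces the
cost matrix to O(n·band) cells.

Raw DTW costs have no fixed range, which hampers interpretation.  The bounded
variant implemented here (``time_dtw_distance``) therefore

1. z-normalises each series (zero mean, unit population variance), removing
   the orders-of-magnitude abundance differences typical of microbiome data;
2. computes the band-constrained DTW cost between the normalised series;
3. divides by the mean of each series' sum of absolute differences (SAD) from
   its mirror image, the reflection about the mean (``mirror(s) = -s`` after
   z-normalisation) — the natural maximal-dissimilarity scale;
4. clips at 1 to guard residual pathological warps.

The result lies in [0, 1]: 0 for identical shapes, 1 for shapes as dissimilar
as a curve and its reflection.  Pearson correlation (distance 1 - r) is
offered as a classical alternative.  Pairwise matrices feed average-linkage
hierarchical clustering with Newick tree export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_ingest import TimeSeriesDataset

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "default_band",
    "dtw_distance",
    "time_dtw_distance",
    "pearson_matrix",
    "distance_matrix",
    "cluster_taxa",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    metric: str  # dtw | time_dtw | pearson_distance | jsd

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class ClusterTree:
    labels: list[str]
    linkage_matrix: np.ndarray
    linkage: str

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) from cutting the tree into k groups."""
        return hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Newick string; branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node):
            if node.is_leaf():
                return self.labels[node.id].replace(" ", "_")
            l, r = fmt(node.left), fmt(node.right)
            bl_l = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
            bl_r = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
            return f"({l}:{max(bl_l, 0.0):.6g},{r}:{max(bl_r, 0.0):.6g})"

        return fmt(tree) + ";"


def default_band(n_time: int) -> int:
    """Sakoe-Chiba half-width: the classical 10% of series length, floor 10."""
    return max(10, math.ceil(0.1 * n_time))


def dtw_distance(x, y, band: int | None = None) -> float:
    """Band-constrained DTW alignment cost with local cost |x_i - y_j|.

    Symmetric step pattern (match/insert/delete, unweighted).  ``band`` is the
    Sakoe-Chiba half-width; ``None`` evaluates the full cost matrix.  When the
    lengths differ the band must be at least their difference, otherwise no
    path from corner to corner exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("DTW requires non-empty series")
    if band is not None:
        if band < abs(n - m):
            raise ValueError(
                f"band {band} infeasible for lengths {n} and {m} "
                f"(needs >= {abs(n - m)})"
            )
        w = max(band, abs(n - m))
    else:
        w = max(n, m)
    inf = float("inf")
    prev = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, inf)
        lo = max(1, i - w)
        hi = min(m, i + w)
        cost = np.abs(x[i - 1] - y[lo - 1 : hi])
        for j in range(lo, hi + 1):
            cur[j] = cost[j - lo] + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return float(prev[m])


def _znorm(s: np.ndarray, name: str = "") -> np.ndarray:
    s = np.asarray(s, dtype=float)
    sd = s.std()  # population sd
    if sd == 0:
        raise ValueError(
            f"constant series{f' ({name})' if name else ''}: z-normalization "
            "undefined"
        )
    return (s - s.mean()) / sd


def time_dtw_distance(x, y, band: int | None = None, *,
                      names: tuple[str, str] = ("", "")) -> float:
    """Bounded DTW distance in [0, 1] between two series (see module docs)."""
    xz = _znorm(x, names[0])
    yz = _znorm(y, names[1])
    if band is None:
        band = default_band(max(xz.size, yz.size))
    d = dtw_distance(xz, yz, band=band)
    # SAD against the mirror image -s; after z-normalisation this is 2*sum|s|
    normalizer = (np.abs(2 * xz).sum() + np.abs(2 * yz).sum()) / 2.0
    return min(1.0, d / normalizer)


def pearson_matrix(dataset: TimeSeriesDataset) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise Pearson correlation; returns (distance 1-r matrix, raw r).

    Constant taxa have undefined correlation; their rows/columns are NaN in
    both outputs.
    """
    if dataset.n_times < 3:
        raise ValueError("Pearson matrix needs >= 3 time points")
    a = dataset.abundance
    sd = a.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(a)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(dataset.taxa), dist, "pearson_distance"), r


def distance_matrix(
    dataset: TimeSeriesDataset, metric: str = "time_dtw", band: int | None = None
) -> DistanceMatrix:
    """Pairwise taxa distance matrix under dtw / time_dtw / pearson."""
    if metric == "pearson":
        return pearson_matrix(dataset)[0]
    if metric not in ("dtw", "time_dtw"):
        raise ValueError(f"unknown metric {metric!r}")
    fn = dtw_distance if metric == "dtw" else time_dtw_distance
    n = dataset.n_taxa
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "time_dtw":
                d = time_dtw_distance(
                    dataset.abundance[i], dataset.abundance[j], band,
                    names=(dataset.taxa[i], dataset.taxa[j]),
                )
            else:
                d = fn(dataset.abundance[i], dataset.abundance[j], band)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(dataset.taxa), values, metric)


def cluster_taxa(dist: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of the labels of a complete distance matrix."""
    if np.isnan(dist.values).any():
        bad = [dist.labels[i] for i in np.flatnonzero(np.isnan(dist.values).any(axis=1))]
        raise ValueError(f"distance matrix has missing entries for: {bad}")
    z = hierarchy.linkage(dist.condensed(), method=linkage)
    return ClusterTree(list(dist.labels), z, linkage)
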