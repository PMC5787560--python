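"""Community-state typing of time points.

Time points with similar taxonomic composition form a "community state".
Each sample column is scaled to a probability distribution over taxa, and
pairwise dissimilarity between time points is the Jensen-Shannon divergence
(natural log, hence bounded by ln 2):

    JSD(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q)/2.

The JSD matrix is clustered with K-medoids (PAM), which — unlike K-means —
works directly on a precomputed dissimilarity and is robust to outliers.
Medoids are initialised with the deterministic greedy BUILD step; the SWAP
phase then exchanges medoids while the total within-cluster distance to
medoids decreases.  The seed only breaks exact ties.  Per-cluster "driver"
taxa are ranked by the spread of their mean relative abundance across
clusters (max - min), largest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .io_ingest import TimeSeriesDataset
from .preprocess import filter_rare_taxa, normalize_relative
from .similarity import DistanceMatrix, cluster_taxa, distance_matrix

__all__ = [
    "CommunityStateAssignment",
    "jensen_shannon",
    "jsd_matrix",
    "kmedoids",
    "community_state_report",
    "silhouette_table",
]


@dataclass
class CommunityStateAssignment:
    times: np.ndarray
    labels: np.ndarray  # cluster id (0..k-1) per time point
    k: int
    medoids: np.ndarray  # time-point indices
    driver_table: pd.DataFrame | None = None  # taxa x clusters mean rel. abund.
    objective: float = float("nan")


def jensen_shannon(p, q) -> float:
    """JSD between two probability vectors, natural log, in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def jsd_matrix(dataset: TimeSeriesDataset) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between time-point compositions."""
    totals = dataset.abundance.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample(s) at time indices {zero.tolist()}: "
            "composition undefined"
        )
    probs = dataset.abundance / totals
    t = dataset.n_times
    values = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            values[i, j] = values[j, i] = jensen_shannon(probs[:, i], probs[:, j])
    labels = [repr(float(x)) for x in dataset.times]
    return DistanceMatrix(labels, values, "jsd")


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    d = dist[:, medoids]
    labels = d.argmin(axis=1)
    return labels, float(d.min(axis=1).sum())


def kmedoids(
    dist: DistanceMatrix, k: int, seed: int = 0, max_iter: int = 200
) -> CommunityStateAssignment:
    """PAM clustering (BUILD + SWAP) on a precomputed dissimilarity matrix.

    The objective — total distance of points to their cluster medoid — is
    non-increasing across swap iterations.  BUILD is deterministic; ``seed``
    resolves exact ties in candidate scores.
    """
    d = dist.values
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n}, got {k}")
    rng = np.random.default_rng(seed)

    def pick_min(scores: np.ndarray, exclude: set[int]) -> int:
        scores = scores.copy()
        scores[list(exclude)] = np.inf
        best = scores.min()
        ties = np.flatnonzero(np.isclose(scores, best, rtol=0, atol=0))
        return int(ties[0] if ties.size == 1 else rng.choice(ties))

    # BUILD: first medoid minimises total distance, then greedy additions
    medoids: list[int] = [pick_min(d.sum(axis=1), set())]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.array([
            np.minimum(d[:, c], nearest).sum() for c in range(n)
        ])
        medoids.append(pick_min(gains, set(medoids)))

    medoid_arr = np.array(medoids)
    labels, objective = _assign(d, medoid_arr)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for cand in range(n):
                if cand in medoid_arr:
                    continue
                trial = medoid_arr.copy()
                trial[mi] = cand
                _, obj = _assign(d, trial)
                if obj < objective - 1e-12:
                    medoid_arr, objective = trial, obj
                    improved = True
        labels, objective = _assign(d, medoid_arr)
        if not improved:
            break
    times = np.array([float(x) for x in dist.labels]) if all(
        _is_float(x) for x in dist.labels
    ) else np.arange(n, dtype=float)
    return CommunityStateAssignment(
        times=times, labels=labels, k=k, medoids=medoid_arr, objective=objective
    )


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def community_state_report(
    dataset: TimeSeriesDataset,
    k: int = 2,
    rare_cutoff: float = 0.0,
    seed: int = 0,
    band: int | None = None,
) -> tuple[CommunityStateAssignment, "np.ndarray"]:
    """Full community-state workflow.

    Rare-filter, scale to relative abundance, JSD over time points, K-medoids
    at the chosen ``k``, driver table, and a hierarchical ordering of taxa
    (average-linkage on the bounded DTW distance) for heatmap display.
    Returns the assignment and the taxa leaf order.
    """
    data = filter_rare_taxa(dataset, rare_cutoff) if rare_cutoff else dataset
    if data.normalization == "none":
        data = normalize_relative(data)
    dist = jsd_matrix(data)
    assignment = kmedoids(dist, k, seed)
    assignment.times = data.times

    rel = data.abundance / np.where(
        data.abundance.sum(axis=0) > 0, data.abundance.sum(axis=0), 1.0
    )
    cluster_means = np.column_stack([
        rel[:, assignment.labels == c].mean(axis=1) for c in range(k)
    ])
    contrast = cluster_means.max(axis=1) - cluster_means.min(axis=1)
    order = np.argsort(-contrast, kind="stable")
    driver = pd.DataFrame(
        cluster_means[order],
        index=[data.taxa[i] for i in order],
        columns=[f"state_{c}" for c in range(k)],
    )
    driver["contrast"] = contrast[order]
    assignment.driver_table = driver

    leaf_order = data.taxa
    if data.n_taxa >= 3 and all(data.abundance.std(axis=1) > 0):
        tree = cluster_taxa(distance_matrix(data, "time_dtw", band))
        leaf_order = tree.leaf_order()
    return assignment, np.array(leaf_order)


def silhouette_table(dist: DistanceMatrix, k_range=range(2, 7), seed: int = 0) -> pd.DataFrame:
    """Mean silhouette width for each candidate k, to guide the user's choice."""
    from sklearn.metrics import silhouette_score

    rows = []
    n = dist.values.shape[0]
    for k in k_range:
        if k >= n:
            continue
        labels = kmedoids(dist, k, seed).labels
        if len(set(labels.tolist())) < 2:
            continue
        rows.append(
            {"k": k,
             "silhouette": float(
                 silhouette_score(dist.values, labels, metric="precomputed")
             )}
        )
    return pd.DataFrame(rows)
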