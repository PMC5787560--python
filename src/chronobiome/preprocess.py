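"""Normalization and filtering of longitudinal abundance matrices.

Two normalization routes are offered, mirroring common microbiome practice:
scaling each sample to proportions (relative normalization) and rarefaction
(without-replacement subsampling of every sample to an even depth, i.e. a
multivariate-hypergeometric draw).  Rarefaction curves — expected richness as
a function of subsampling depth — help choose a depth.  The module also hosts
the small presentation helpers of the trend-exploration workflow: rare-taxa
filtering, log scaling, trailing moving averages and quartile segregation of
taxa by abundance scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_ingest import TimeSeriesDataset, ValidationError

__all__ = [
    "RarefactionCurve",
    "normalize_relative",
    "rarefy",
    "rarefaction_curve",
    "filter_rare_taxa",
    "log_scale",
    "moving_average",
    "quartile_segregate",
]


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    mean_richness: np.ndarray
    replicates: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tdepth\tmean_richness\n")
            for d, r in zip(self.depths, self.mean_richness):
                fh.write(f"{self.sample_id}\t{int(d)}\t{float(r)!r}\n")


def normalize_relative(dataset: TimeSeriesDataset) -> TimeSeriesDataset:
    """Scale every time-point column to proportions summing to 1.

    All-zero columns are left as zeros with a warning (they carry no
    compositional information).
    """
    if dataset.normalization != "none":
        raise ValidationError(
            f"dataset already normalized ({dataset.normalization})"
        )
    totals = dataset.abundance.sum(axis=0)
    zero_cols = np.flatnonzero(totals == 0)
    if zero_cols.size:
        warnings.warn(
            f"all-zero columns at time indices {zero_cols.tolist()} left "
            "unnormalized",
            stacklevel=2,
        )
    safe = np.where(totals > 0, totals, 1.0)
    return dataset.copy_with(
        abundance=dataset.abundance / safe, normalization="relative"
    )


def rarefy(dataset: TimeSeriesDataset, depth: int, seed: int) -> TimeSeriesDataset:
    """Subsample each column without replacement to exactly ``depth`` reads.

    Columns whose total is below ``depth`` are dropped with a warning naming
    them.  Counts must be integers (rarefaction of proportions is undefined).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = dataset.abundance
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError(
            "rarefaction requires integer counts; skip rarefaction for "
            "pre-normalized data"
        )
    counts = np.round(counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        dropped = [dataset.sample_ids[j] if dataset.sample_ids else str(j)
                   for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"columns below rarefaction depth {depth} dropped: {dropped}",
            stacklevel=2,
        )
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(counts[:, j], depth))
    return dataset.copy_with(
        times=dataset.times[keep],
        conditions=[c for c, k in zip(dataset.conditions, keep) if k],
        sample_ids=(
            [s for s, k in zip(dataset.sample_ids, keep) if k]
            if dataset.sample_ids else None
        ),
        abundance=np.column_stack(cols).astype(float)
        if cols else np.empty((dataset.n_taxa, 0)),
        normalization=f"rarefied:{depth}",
    )


def rarefaction_curve(
    dataset: TimeSeriesDataset,
    sample_id: str,
    depths,
    replicates: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean observed richness over repeated subsamples at each depth."""
    if dataset.sample_ids is None or sample_id not in dataset.sample_ids:
        raise ValueError(f"unknown sample {sample_id!r}")
    col = np.round(
        dataset.abundance[:, dataset.sample_ids.index(sample_id)]
    ).astype(np.int64)
    total = int(col.sum())
    depths = np.asarray(sorted(int(d) for d in depths))
    if depths.size and depths[-1] > total:
        raise ValueError(
            f"depth {depths[-1]} exceeds sample total {total} for {sample_id!r}"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(depths.size)
    for i, d in enumerate(depths):
        rich = [
            int(np.count_nonzero(rng.multivariate_hypergeometric(col, int(d))))
            for _ in range(replicates)
        ]
        means[i] = float(np.mean(rich))
    return RarefactionCurve(sample_id, depths, means, replicates)


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected richness of a without-replacement subsample.

    E[S] = sum_i 1 - C(N - n_i, d) / C(N, d), used as an oracle for the
    Monte-Carlo curve.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    denom = math.comb(total, depth)
    return float(sum(
        1.0 - math.comb(total - int(n), depth) / denom
        for n in counts if n > 0
    ))


def filter_rare_taxa(dataset: TimeSeriesDataset, cutoff: float) -> TimeSeriesDataset:
    """Keep taxa present (abundance > 0) in at least ``cutoff`` of time points."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    prevalence = (dataset.abundance > 0).mean(axis=1)
    keep = np.flatnonzero(prevalence >= cutoff)
    return dataset.copy_with(
        taxa=[dataset.taxa[i] for i in keep],
        abundance=dataset.abundance[keep],
        lineages=(
            [dataset.lineages[i] for i in keep] if dataset.lineages else None
        ),
    )


def log_scale(dataset: TimeSeriesDataset, pseudocount: float | None = None) -> np.ndarray:
    """Elementwise log10(x + pseudocount) view; the dataset is not modified.

    The default pseudocount is 1 for count-scale data and half the smallest
    nonzero value for proportion-scale data.
    """
    if pseudocount is None:
        positive = dataset.abundance[dataset.abundance > 0]
        if dataset.normalization == "relative" and positive.size:
            pseudocount = float(positive.min()) / 2.0
        else:
            pseudocount = 1.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log10(dataset.abundance + pseudocount)


def moving_average(series, window: int) -> np.ndarray:
    """Trailing mean over the last ``window`` points (shorter prefix windows).

    A trailing (rather than centred) window avoids look-ahead leakage when the
    smoothed series feeds further time-series analysis.
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > series.size:
        raise ValueError("window exceeds series length")
    out = np.empty_like(series)
    csum = np.concatenate([[0.0], np.cumsum(series)])
    for t in range(series.size):
        lo = max(0, t - window + 1)
        out[t] = (csum[t + 1] - csum[lo]) / (t + 1 - lo)
    return out


def quartile_segregate(dataset: TimeSeriesDataset) -> dict[str, str]:
    """Assign each taxon to an abundance quartile Q1 (lowest) .. Q4 (highest).

    Taxa are ranked by mean abundance over time; ties are broken by label so
    the assignment is deterministic.  With fewer than four taxa a single group
    is returned with a warning.
    """
    if dataset.n_taxa < 4:
        warnings.warn("fewer than 4 taxa; returning a single group", stacklevel=2)
        return {t: "Q1" for t in dataset.taxa}
    means = dataset.abundance.mean(axis=1)
    order = sorted(range(dataset.n_taxa), key=lambda i: (means[i], dataset.taxa[i]))
    n = dataset.n_taxa
    out: dict[str, str] = {}
    for rank, i in enumerate(order):
        q = min(3, (4 * rank) // n)
        out[dataset.taxa[i]] = f"Q{q + 1}"
    return out
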