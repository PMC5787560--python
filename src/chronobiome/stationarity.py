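"""Unit-root screening of per-taxon abundance trajectories.

A taxon whose series carries a unit root (an autoregressive coefficient at
one) never reverts after a shock — its mean and variance drift, so it is
non-stationary.  The augmented Dickey-Fuller (ADF) test takes the unit root as
its null hypothesis; the more negative the test statistic, the stronger the
evidence for stationarity.  We run the test per taxon (after rare-taxa
filtering) and call a taxon stationary when the unit-root null is rejected at
level ``alpha``.

Lag order is selected by AIC up to trunc((n-1)^(1/3)); the regression includes
a constant only (relative-abundance series have no a-priori deterministic
trend), configurable to constant+trend.  Raw p-values drive the calls, as the
screen is exploratory; a Benjamini-Hochberg-adjusted column is emitted
alongside for cautious users.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import adfuller

from .io_ingest import TimeSeriesDataset
from .preprocess import filter_rare_taxa

__all__ = ["ADFResult", "adf_test", "stationarity_report"]

_REGRESSION = {"constant": "c", "constant_trend": "ct"}


@dataclass
class ADFResult:
    taxon: str
    statistic: float
    p_value: float
    n_lags: int
    stationary: bool
    adjusted_p: float | None = None


def adf_test(
    series,
    max_lag: int | None = None,
    regression: str = "constant",
    alpha: float = 0.05,
    taxon: str = "",
) -> ADFResult:
    """Augmented Dickey-Fuller test of one series.

    ``max_lag=None`` selects the lag order by AIC up to trunc((n-1)^(1/3)).
    A constant series is degenerate (the regression is singular) and raises
    rather than being reported as stationary.
    """
    series = np.asarray(series, dtype=float)
    if regression not in _REGRESSION:
        raise ValueError(f"regression must be one of {sorted(_REGRESSION)}")
    if np.allclose(series, series[0]):
        raise ValueError(
            f"constant series{f' ({taxon})' if taxon else ''} is untestable"
        )
    n = series.size
    if max_lag is None:
        max_lag = int(np.floor((n - 1) ** (1 / 3)))
    stat, p, used_lag, *_ = adfuller(
        series,
        maxlag=max_lag,
        regression=_REGRESSION[regression],
        autolag="AIC",
    )
    return ADFResult(
        taxon=taxon,
        statistic=float(stat),
        p_value=float(p),
        n_lags=int(used_lag),
        stationary=bool(p < alpha),
    )


def stationarity_report(
    dataset: TimeSeriesDataset,
    alpha: float = 0.05,
    rare_cutoff: float = 0.0,
    regression: str = "constant",
) -> list[ADFResult]:
    """One ADF result per taxon surviving the rare-taxa filter.

    Degenerate (constant) taxa are recorded with NaN statistic and
    ``stationary=False`` rather than aborting the batch.  BH-adjusted
    p-values are filled in across the testable taxa.
    """
    filtered = filter_rare_taxa(dataset, rare_cutoff) if rare_cutoff else dataset
    results: list[ADFResult] = []
    for taxon, row in zip(filtered.taxa, filtered.abundance):
        try:
            results.append(
                adf_test(row, regression=regression, alpha=alpha, taxon=taxon)
            )
        except ValueError:
            results.append(
                ADFResult(taxon, float("nan"), float("nan"), 0, False)
            )
    testable = [r for r in results if np.isfinite(r.p_value)]
    if testable:
        _, adj, *_ = multipletests(
            [r.p_value for r in testable], method="fdr_bh"
        )
        for r, a in zip(testable, adj):
            r.adjusted_p = float(a)
    return results


def report_to_tsv(results: list[ADFResult], path, normalization: str = "none") -> None:
    with open(path, "w") as fh:
        fh.write(f"#normalization={normalization}\n")
        fh.write("taxon\tstatistic\tp_value\tadjusted_p\tn_lags\tcall\n")
        for r in results:
            adj = "" if r.adjusted_p is None else repr(r.adjusted_p)
            call = "stationary" if r.stationary else (
                "untestable" if not np.isfinite(r.p_value) else "non-stationary"
            )
            fh.write(
                f"{r.taxon}\t{r.statistic!r}\t{r.p_value!r}\t{adj}\t{r.n_lags}\t{call}\n"
            )
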