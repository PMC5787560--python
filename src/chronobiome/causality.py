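"""Directed interaction networks from Granger causality.

Taxon A Granger-causes taxon B when past values of A improve the prediction
of B beyond B's own past.  Pairwise testing compares two nested least-squares
regressions — B_t on its own lags (restricted) versus B_t on its own lags plus
A's lags (unrestricted) — with an F-test on the reduction in residual sum of
squares:

    F = ((RSS_r - RSS_u) / q) / (RSS_u / (n - k)),

q added regressors, k parameters of the unrestricted model.  With many taxa,
the multivariate Granger-Lasso alternative regresses each taxon's present on
the lag-stacked past of *all* taxa under an L1 penalty; predictors whose
coefficients survive the shrinkage define incoming edges.  The intersection
of both edge sets trades recall for precision.

Pairwise p-values are Benjamini-Hochberg corrected across all ordered pairs
before thresholding.  Series are z-standardised before the Lasso so the
shared penalty is scale-fair; the penalty is chosen by BIC and surviving
coefficients are additionally thresholded (|b| > 0.1 in standardised units),
the classical thresholded-Lasso remedy for the L1 penalty's tendency to
retain small noise coefficients at prediction-optimal regularisation.  Non-stationary series are not differenced — stationarity
calls are overlaid as node attributes instead, as a visible interpretive
caveat (Granger predictions are statistical, not mechanistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoLarsIC, LinearRegression
from statsmodels.stats.multitest import multipletests

from .io_ingest import TimeSeriesDataset
from .preprocess import filter_rare_taxa

__all__ = [
    "CausalEdge",
    "pairwise_granger",
    "granger_lasso",
    "build_network",
    "graph_to_edgelist_tsv",
]

#: standardized-coefficient magnitude below which a Lasso edge is discarded.
#: The plain Lasso at a prediction-optimal penalty retains many tiny noise
#: coefficients; thresholding restores consistent support recovery.
COEF_THRESHOLD = 0.1


@dataclass
class CausalEdge:
    source: str
    target: str
    method: str  # pairwise | lasso | intersection
    statistic: float
    lag: int
    p_value: float | None = None
    adjusted_p: float | None = None


def _lag_design(series_matrix: np.ndarray, lag: int) -> tuple[np.ndarray, int]:
    """Stack lagged copies of each row-series into a (T-lag, n*lag) design."""
    n, t = series_matrix.shape
    cols = [
        series_matrix[i, lag - ell - 1 : t - ell - 1]
        for i in range(n)
        for ell in range(lag)
    ]
    return np.column_stack(cols), t - lag


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def pairwise_granger(x, y, lag: int = 1) -> tuple[float, float]:
    """Test whether ``x`` Granger-causes ``y`` at lag order ``lag``.

    Returns the F statistic of the nested-model comparison and its p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if x.size != y.size:
        raise ValueError("series lengths differ")
    t = y.size
    n_obs = t - lag
    if n_obs <= 2 * lag + 1:
        raise ValueError(f"series too short (T={t}) for lag {lag}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant series make the Granger design singular")
    target = y[lag:]
    own, _ = _lag_design(y[None, :], lag)
    other, _ = _lag_design(x[None, :], lag)
    intercept = np.ones((n_obs, 1))
    rss_r = _ols_rss(np.hstack([intercept, own]), target)
    rss_u = _ols_rss(np.hstack([intercept, own, other]), target)
    k = 1 + 2 * lag
    df_den = n_obs - k
    if df_den <= 0:
        raise ValueError("not enough observations for the unrestricted model")
    if rss_u <= 0:
        return float("inf"), 0.0
    f = ((rss_r - rss_u) / lag) / (rss_u / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, lag, df_den))
    return float(f), p


def granger_lasso(
    dataset: TimeSeriesDataset,
    lag: int = 1,
    criterion: str = "bic",
    coef_threshold: float = COEF_THRESHOLD,
    penalty: float | None = None,
) -> dict[tuple[str, str], float]:
    """Sparse multivariate Granger edges via thresholded L1 regressions.

    For each target taxon, its present values are regressed on the lagged
    past of all taxa (z-standardised) with an L1 penalty selected by
    ``criterion`` (BIC by default).  Edge (i -> j) exists iff some lag of
    taxon i keeps a coefficient of magnitude above ``coef_threshold`` in
    taxon j's model; the stored statistic is the largest absolute surviving
    coefficient.  ``penalty`` bypasses the information criterion and fits at
    a fixed regularisation strength (0 reduces to least squares).
    """
    a = dataset.abundance
    n, t = a.shape
    if t <= 2 * lag + 2:
        raise ValueError(f"series too short (T={t}) for Granger-Lasso at lag {lag}")
    sd = a.std(axis=1)
    usable = np.flatnonzero(sd > 0)
    if usable.size < n:
        dropped = [dataset.taxa[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"constant taxa dropped from Lasso: {dropped}", stacklevel=2)
    z = (a[usable] - a[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    X, _ = _lag_design(z, lag)
    edges: dict[tuple[str, str], float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for jj, j in enumerate(usable):
            y = z[jj, lag:]
            if penalty is None:
                model = LassoLarsIC(criterion=criterion).fit(X, y)
            elif penalty == 0:
                model = LinearRegression().fit(X, y)
            else:
                model = Lasso(alpha=penalty).fit(X, y)
            coef = model.coef_.reshape(usable.size, lag)
            for ii, i in enumerate(usable):
                if i == j:
                    continue
                mag = float(np.abs(coef[ii]).max())
                if mag > coef_threshold:
                    edges[(dataset.taxa[i], dataset.taxa[j])] = mag
    return edges


def build_network(
    dataset: TimeSeriesDataset,
    method: str = "intersection",
    lag: int = 1,
    alpha: float = 0.05,
    rare_cutoff: float = 0.0,
    stationary_flags: dict[str, bool] | None = None,
    use_adjusted_p: bool = True,
) -> nx.DiGraph:
    """Directed causality graph over taxa.

    ``pairwise`` keeps ordered pairs whose BH-adjusted Granger p-value is
    below ``alpha`` (set ``use_adjusted_p=False`` to threshold raw p-values;
    both columns are exported either way); ``lasso`` keeps nonzero-support
    edges; ``intersection`` keeps edges present in both.  Node attributes
    carry stationarity flags when supplied.
    """
    if method not in ("pairwise", "lasso", "intersection"):
        raise ValueError(f"unknown method {method!r}")
    data = filter_rare_taxa(dataset, rare_cutoff) if rare_cutoff else dataset
    if data.n_taxa < 3:
        raise ValueError(
            f"only {data.n_taxa} taxa remain after rare filtering; need >= 3"
        )
    g = nx.DiGraph()
    for taxon in data.taxa:
        g.add_node(
            taxon,
            stationary=bool(stationary_flags.get(taxon))
            if stationary_flags else None,
        )

    pairwise_edges: dict[tuple[str, str], CausalEdge] = {}
    if method in ("pairwise", "intersection"):
        records = []
        for i, src in enumerate(data.taxa):
            for j, dst in enumerate(data.taxa):
                if i == j:
                    continue
                try:
                    f, p = pairwise_granger(
                        data.abundance[i], data.abundance[j], lag
                    )
                except ValueError:
                    continue
                records.append((src, dst, f, p))
        if records:
            _, adj, *_ = multipletests([r[3] for r in records], method="fdr_bh")
            for (src, dst, f, p), ap in zip(records, adj):
                thresh_p = ap if use_adjusted_p else p
                if thresh_p < alpha:
                    pairwise_edges[(src, dst)] = CausalEdge(
                        src, dst, "pairwise", f, lag, p, float(ap)
                    )

    lasso_edges: dict[tuple[str, str], float] = {}
    if method in ("lasso", "intersection"):
        lasso_edges = granger_lasso(data, lag)

    if method == "pairwise":
        chosen = pairwise_edges.values()
    elif method == "lasso":
        chosen = [
            CausalEdge(s, t, "lasso", mag, lag)
            for (s, t), mag in lasso_edges.items()
        ]
    else:
        chosen = [
            CausalEdge(
                s, t, "intersection", e.statistic, lag, e.p_value, e.adjusted_p
            )
            for (s, t), e in pairwise_edges.items()
            if (s, t) in lasso_edges
        ]
    for e in chosen:
        g.add_edge(
            e.source, e.target, method=e.method, statistic=e.statistic,
            p_value=e.p_value, adjusted_p=e.adjusted_p, lag=e.lag,
        )
    return g


def graph_to_edgelist_tsv(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tmethod\tstatistic\tp_value\tadjusted_p\tlag\n")
        for u, v, d in sorted(g.edges(data=True)):
            p = "" if d.get("p_value") is None else repr(d["p_value"])
            ap = "" if d.get("adjusted_p") is None else repr(d["adjusted_p"])
            fh.write(
                f"{u}\t{v}\t{d['method']}\t{d['statistic']!r}\t{p}\t{ap}\t{d['lag']}\n"
            )


def query_node(g: nx.DiGraph, node: str, direction: str = "causes") -> list[str]:
    """Neighbours of a node: taxa it Granger-causes, or is caused by."""
    if node not in g:
        raise KeyError(f"taxon {node!r} not in graph")
    if direction == "causes":
        return sorted(g.successors(node))
    if direction == "caused-by":
        return sorted(g.predecessors(node))
    raise ValueError("direction must be 'causes' or 'caused-by'")
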