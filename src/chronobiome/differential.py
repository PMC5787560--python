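"""Two-window differential abundance of taxa.

Given two non-overlapping stretches of the timeline (e.g. before and after a
perturbation such as an antibiotic course), each taxon is summarised by its
mean abundance per window, a log2 fold change

    lfc = log2((mean2 + pc) / (mean1 + pc)),

with pseudocount pc set to half the smallest nonzero abundance of the
dataset, and a two-sided Wilcoxon rank-sum test comparing the two windows'
abundance vectors.  P-values are Benjamini-Hochberg corrected across taxa.
Taxa present in window 1 but entirely absent from window 2 are flagged as
eliminated.  Records are sorted by |lfc| descending, so the most strongly
shifted taxa head the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_ingest import TimeSeriesDataset

__all__ = ["DifferentialRecord", "compare_ranges", "ranges_from_conditions"]


@dataclass
class DifferentialRecord:
    taxon: str
    mean1: float
    mean2: float
    log_fold_change: float
    p_value: float
    adjusted_p: float
    eliminated: bool


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration for small tie-free windows, normal approximation
    with tie and continuity correction otherwise.  Fully tied data carry no
    evidence either way and return p = 1.
    """
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    small = a.size <= 20 and b.size <= 20
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (small and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_ranges(
    dataset: TimeSeriesDataset,
    range1: tuple[int, int],
    range2: tuple[int, int],
    pseudocount: float | None = None,
) -> list[DifferentialRecord]:
    """Differential-abundance records between two inclusive index windows."""
    (a1, b1), (a2, b2) = range1, range2
    t = dataset.n_times
    for a, b in ((a1, b1), (a2, b2)):
        if not (0 <= a <= b < t):
            raise ValueError(f"range {a}:{b} outside 0..{t - 1}")
        if b - a + 1 < 3:
            raise ValueError(f"range {a}:{b} has fewer than 3 time points")
    if max(a1, a2) <= min(b1, b2):
        raise ValueError(f"ranges {range1} and {range2} overlap")
    if pseudocount is None:
        positive = dataset.abundance[dataset.abundance > 0]
        pseudocount = float(positive.min()) / 2.0 if positive.size else 0.5

    records = []
    pvals = []
    for taxon, row in zip(dataset.taxa, dataset.abundance):
        w1 = row[a1 : b1 + 1]
        w2 = row[a2 : b2 + 1]
        m1, m2 = float(w1.mean()), float(w2.mean())
        # difference of logs (not log of ratio) so that swapping the windows
        # negates the fold change exactly in floating point
        lfc = float(np.log2(m2 + pseudocount) - np.log2(m1 + pseudocount))
        p = _rank_sum_p(w1, w2)
        records.append(
            DifferentialRecord(
                taxon, m1, m2, lfc, p, np.nan,
                eliminated=bool(m1 > 0 and np.all(w2 == 0)),
            )
        )
        pvals.append(p)
    _, adj, *_ = multipletests(pvals, method="fdr_bh")
    for rec, ap in zip(records, adj):
        rec.adjusted_p = float(ap)
    records.sort(key=lambda r: (-abs(r.log_fold_change), r.taxon))
    return records


def ranges_from_conditions(
    dataset: TimeSeriesDataset, cond1: str, cond2: str
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Index windows spanned by two condition labels (must be contiguous)."""
    out = []
    for cond in (cond1, cond2):
        idx = [i for i, c in enumerate(dataset.conditions) if c == cond]
        if not idx:
            raise ValueError(f"condition {cond!r} not present")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"condition {cond!r} is not a contiguous stretch")
        out.append((idx[0], idx[-1]))
    return out[0], out[1]


def records_to_tsv(records: list[DifferentialRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon\tmean1\tmean2\tlog_fold_change\tp_value\tadjusted_p\teliminated\n"
        )
        for r in records:
            fh.write(
                f"{r.taxon}\t{r.mean1!r}\t{r.mean2!r}\t{r.log_fold_change!r}\t"
                f"{r.p_value!r}\t{r.adjusted_p!r}\t{int(r.eliminated)}\n"
            )
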