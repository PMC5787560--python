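"""Diversity summaries and prevalence classification of taxa over time.

Richness counts the taxa observed at each time point; evenness is summarised
by the Shannon index H = -sum_i p_i ln p_i over the taxa proportions p_i of a
sample.  Taxa are further classified by their temporal occupancy pattern:

* **core** — present at every time point;
* **persistent** — present in more than 20% of time points, with at least 90%
  of those presences forming one consecutive run;
* **transient** — present in at least 60% of time points, with the longest
  consecutive run covering at most 75% of the presences (frequent appearance
  and disappearance);
* **other** — none of the above.

"X% of the observations being consecutive" is formalised as the longest
consecutive presence run divided by the total number of presence points.
The rules can overlap; precedence core > persistent > transient makes calls
mutually exclusive.  All thresholds are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_ingest import TimeSeriesDataset

__all__ = [
    "PrevalenceCall",
    "DiversitySeries",
    "richness",
    "shannon_index",
    "diversity_series",
    "longest_run",
    "classify_prevalence",
]


@dataclass
class PrevalenceCall:
    taxon: str
    prevalence: float
    longest_run_fraction: float
    call: str  # core | persistent | transient | other


@dataclass
class DiversitySeries:
    times: np.ndarray
    richness: np.ndarray
    shannon: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\trichness\tshannon\n")
            for t, r, h in zip(self.times, self.richness, self.shannon):
                fh.write(f"{float(t)!r}\t{int(r)}\t{float(h)!r}\n")


def richness(dataset: TimeSeriesDataset) -> np.ndarray:
    """Number of taxa with abundance > 0 at each time point."""
    return np.count_nonzero(dataset.abundance > 0, axis=0)


def shannon_index(column) -> float:
    """Shannon diversity H = -sum p_i ln p_i of one sample (natural log).

    Proportions are computed over the column total, so counts and proportions
    give identical values; zero-abundance taxa contribute nothing.  An
    all-zero column has undefined diversity and returns NaN with a warning.
    """
    column = np.asarray(column, dtype=float)
    total = column.sum()
    if total <= 0:
        warnings.warn("all-zero sample: Shannon index undefined", stacklevel=2)
        return float("nan")
    p = column[column > 0] / total
    return float(-(p * np.log(p)).sum() + 0.0)  # + 0.0 avoids -0.0


def diversity_series(dataset: TimeSeriesDataset) -> DiversitySeries:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shannon = np.array([shannon_index(c) for c in dataset.abundance.T])
    return DiversitySeries(dataset.times, richness(dataset), shannon)


def longest_run(presence) -> int:
    """Length of the longest consecutive run of True values."""
    best = cur = 0
    for v in presence:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def classify_prevalence(
    dataset: TimeSeriesDataset,
    persistent_prevalence: float = 0.20,
    persistent_run: float = 0.90,
    transient_prevalence: float = 0.60,
    transient_run: float = 0.75,
) -> list[PrevalenceCall]:
    """Classify every taxon as core / persistent / transient / other."""
    if dataset.n_times < 2:
        raise ValueError("prevalence classification needs >= 2 time points")
    calls = []
    for taxon, row in zip(dataset.taxa, dataset.abundance):
        presence = row > 0
        n_present = int(presence.sum())
        prevalence = n_present / dataset.n_times
        run_fraction = (
            longest_run(presence) / n_present if n_present else 0.0
        )
        if prevalence == 1.0:
            call = "core"
        elif (
            prevalence > persistent_prevalence and run_fraction >= persistent_run
        ):
            call = "persistent"
        elif (
            prevalence >= transient_prevalence and run_fraction <= transient_run
        ):
            call = "transient"
        else:
            call = "other"
        calls.append(PrevalenceCall(taxon, prevalence, run_fraction, call))
    return calls


def prevalence_to_tsv(calls: list[PrevalenceCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tprevalence\tlongest_run_fraction\tcall\n")
        for c in calls:
            fh.write(
                f"{c.taxon}\t{c.prevalence!r}\t{c.longest_run_fraction!r}\t{c.call}\n"
            )
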