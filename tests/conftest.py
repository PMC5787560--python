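import numpy as np
import pytest

from chronobiome.io_ingest import TimeSeriesDataset


def make_dataset(abundance, taxa=None, conditions=None, normalization="none",
                 lineages=None):
    abundance = np.asarray(abundance, dtype=float)
    n, t = abundance.shape
    return TimeSeriesDataset(
        source="test",
        taxa=taxa or [f"tax{i}" for i in range(n)],
        times=np.arange(t, dtype=float),
        conditions=conditions or ["c"] * t,
        abundance=abundance,
        normalization=normalization,
        lineages=lineages,
        sample_ids=[f"S{j}" for j in range(t)],
    )


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.integers(0, 50, size=(6, 12)).astype(float))


def dtw_oracle(x, y):
    """Exhaustive enumeration of all warping paths (for short series)."""
    n, m = len(x), len(y)
    best = [float("inf")]

    def rec(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n:
            rec(i + 1, j, cost)
        if j + 1 < m:
            rec(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, cost)

    rec(0, 0, 0.0)
    return best[0]
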