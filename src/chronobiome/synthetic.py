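"""Seeded generators of longitudinal datasets with planted structure.

Every analytical workflow in the package is testable without external
downloads: these generators plant the structure the workflow is meant to
recover (causal edges for the network inference, unit roots for the
stationarity screen, composition blocks for the community-state typing,
shape groups for the temporal clustering, mean shifts for the differential
module) and record the ground truth alongside the dataset.

Latent dynamics are Gaussian; abundances are obtained by exponentiating the
latent paths, giving strictly positive log-normal marginals rather than the
spurious zeros that truncation would create.  All generators are pure
functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_ingest import TimeSeriesDataset

__all__ = [
    "SyntheticDataset",
    "simulate_var",
    "simulate_unit_root_mix",
    "simulate_two_states",
    "simulate_shape_groups",
    "simulate_mean_shift",
    "make_prevalence_fixture",
    "write_fixture_files",
]


@dataclass
class SyntheticDataset:
    dataset: TimeSeriesDataset
    truth: dict = field(default_factory=dict)


def _wrap(abundance: np.ndarray, truth: dict, taxa=None, conditions=None,
          source: str = "synthetic") -> SyntheticDataset:
    n, t = abundance.shape
    return SyntheticDataset(
        dataset=TimeSeriesDataset(
            source=source,
            taxa=taxa or [f"taxon_{i:02d}" for i in range(n)],
            times=np.arange(t, dtype=float),
            conditions=conditions or ["baseline"] * t,
            abundance=abundance,
            sample_ids=[f"{source}_t{j:03d}" for j in range(t)],
        ),
        truth=truth,
    )


def simulate_var(
    adjacency: np.ndarray,
    n_time: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 50,
    transform: str = "exp",
) -> SyntheticDataset:
    """Stable VAR(1) realisation with planted directed edges.

    ``adjacency[i, j]`` is the coefficient of taxon i's past on taxon j's
    present; nonzero off-diagonal entries are the planted causal edges.  The
    latent Gaussian paths are exponentiated to log-normal abundances
    (``transform="none"`` keeps the latent scale, for direct inspection).
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency must be square")
    if np.abs(np.linalg.eigvals(a)).max() >= 1:
        raise ValueError("unstable VAR: spectral radius must be < 1")
    rng = np.random.default_rng(seed)
    total = n_time + burn_in
    z = np.zeros((n, total))
    noise = rng.normal(0.0, noise_sd, size=(n, total))
    for t in range(1, total):
        z[:, t] = a.T @ z[:, t - 1] + noise[:, t]
    z = z[:, burn_in:]
    abundance = np.exp(z) if transform == "exp" else z
    edges = [
        (f"taxon_{i:02d}", f"taxon_{j:02d}")
        for i in range(n) for j in range(n)
        if i != j and a[i, j] != 0
    ]
    return _wrap(abundance, {"edges": edges, "adjacency": a})


def simulate_unit_root_mix(
    n_stationary: int = 10,
    n_unit_root: int = 2,
    n_time: int = 200,
    seed: int = 0,
    noise_sd: float = 1.0,
    transform: str = "exp",
) -> SyntheticDataset:
    """White-noise taxa alongside random-walk (unit-root) taxa.

    Truth records which taxa are non-stationary; the ADF screen should flag
    exactly those.
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(n_stationary + n_unit_root, n_time))
    z = noise.copy()
    z[n_stationary:] = np.cumsum(noise[n_stationary:], axis=1)
    abundance = np.exp(z * 0.25) if transform == "exp" else z
    taxa = [f"taxon_{i:02d}" for i in range(n_stationary + n_unit_root)]
    return SyntheticDataset(
        dataset=_wrap(abundance, {}).dataset,
        truth={"non_stationary": taxa[n_stationary:]},
    )


def simulate_two_states(
    composition_a,
    composition_b,
    block_pattern,
    concentration: float = 200.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Dirichlet draws around two compositions following a block pattern.

    ``block_pattern`` is a sequence over {0, 1} (e.g. [0]*30 + [1]*30, or an
    alternating pattern) assigning each time point its state.  Higher
    ``concentration`` means tighter draws around the state composition.
    """
    pa = np.asarray(composition_a, dtype=float)
    pb = np.asarray(composition_b, dtype=float)
    for name, p in (("composition_a", pa), ("composition_b", pb)):
        if p.ndim != 1 or not np.isclose(p.sum(), 1.0) or (p < 0).any():
            raise ValueError(f"{name} must be a probability vector")
    if pa.size != pb.size:
        raise ValueError("compositions must have equal length")
    pattern = np.asarray(block_pattern, dtype=int)
    rng = np.random.default_rng(seed)
    cols = []
    for state in pattern:
        base = pa if state == 0 else pb
        # keep Dirichlet parameters strictly positive
        cols.append(rng.dirichlet(np.maximum(base, 1e-6) * concentration))
    abundance = np.column_stack(cols)
    return _wrap(
        abundance,
        {"labels": pattern,
         "dominant": (int(np.argmax(pa)), int(np.argmax(pb)))},
    )


def simulate_shape_groups(
    n_per_group: int = 5,
    n_time: int = 60,
    phase_shift: float = np.pi,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> SyntheticDataset:
    """Two groups of sine-shaped taxa differing by a phase shift.

    Within-group phases are jittered by one grid step at most, so the bounded
    DTW distance separates the groups while tolerating small lags.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, 4 * np.pi, n_time)
    rows, labels = [], []
    for g, shift in enumerate((0.0, phase_shift)):
        for _ in range(n_per_group):
            jitter = rng.uniform(-0.5, 0.5) * (grid[1] - grid[0])
            rows.append(
                np.sin(grid + shift + jitter) + rng.normal(0, noise_sd, n_time)
            )
            labels.append(g)
    abundance = np.exp(np.vstack(rows))
    return _wrap(abundance, {"groups": np.array(labels)})


def simulate_mean_shift(
    n_taxa: int = 20,
    n_shifted: int = 3,
    n_per_window: int = 15,
    fold: float = 4.0,
    sigma: float = 0.4,
    seed: int = 0,
) -> SyntheticDataset:
    """Planted between-window fold changes for the differential workflow.

    The first ``n_shifted`` taxa change their log-normal location by
    ``log(fold)`` between the two halves of the timeline; the rest are null.
    """
    rng = np.random.default_rng(seed)
    t = 2 * n_per_window
    base = rng.uniform(1.0, 3.0, size=n_taxa)
    z = rng.normal(0.0, sigma, size=(n_taxa, t))
    abundance = np.exp(base[:, None] + z)
    abundance[:n_shifted, n_per_window:] *= fold
    conditions = ["period1"] * n_per_window + ["period2"] * n_per_window
    sd = _wrap(abundance, {}, conditions=conditions)
    sd.truth = {
        "shifted": sd.dataset.taxa[:n_shifted],
        "range1": (0, n_per_window - 1),
        "range2": (n_per_window, t - 1),
    }
    return sd


def make_prevalence_fixture() -> SyntheticDataset:
    """Hand-constructed presence patterns with known occupancy classes.

    Ten time points per taxon.  Expected calls, derived by hand from the
    occupancy rules (core: all points; persistent: prevalence > 0.2 with
    >= 90% of presences in one run; transient: prevalence >= 0.6 with the
    longest run covering <= 75% of presences):

    * always_there   1111111111  prevalence 1.0               -> core
    * early_bloomer  1110000000  prev 0.3, run 3/3 = 1.0      -> persistent
    * flicker        1010101101  prev 0.6, run 2/6 ~ 0.33     -> transient
    * late_block     0000011111  prev 0.5, run 5/5 = 1.0      -> persistent
    * two_blocks     1111011110  prev 0.8, run 4/8 = 0.5      -> transient
    * barely_moving  1000000000  prev 0.1 (not > 0.2), run 1  -> other
    * mid_run        0111111100  prev 0.7, run 7/7 = 1.0      -> persistent
    * broken_run     1111101111  prev 0.9, run 5/9 ~ 0.56     -> transient
    * odd_one        0011011000  prev 0.4, run 2/4 = 0.5      -> other
    """
    patterns = {
        "always_there": "1111111111",
        "early_bloomer": "1110000000",
        "flicker": "1010101101",
        "late_block": "0000011111",
        "two_blocks": "1111011110",
        "barely_moving": "1000000000",
        "mid_run": "0111111100",
        "broken_run": "1111101111",
        "odd_one": "0011011000",
    }
    expected = {
        "always_there": "core",
        "early_bloomer": "persistent",
        "flicker": "transient",
        "late_block": "persistent",
        "two_blocks": "transient",
        "barely_moving": "other",
        "mid_run": "persistent",
        "broken_run": "transient",
        "odd_one": "other",
    }
    taxa = list(patterns)
    abundance = np.array(
        [[float(c) * (i + 1) for c in patterns[t]] for i, t in enumerate(taxa)]
    )
    sd = _wrap(abundance, {"calls": expected}, taxa=taxa)
    return sd


def write_fixture_files(sd: SyntheticDataset, out_dir, stem: str = "synthetic") -> dict:
    """Write abundance TSV + metadata TSV + truth sidecar; return the paths."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = sd.dataset
    abund_path = out / f"{stem}_abundance.tsv"
    meta_path = out / f"{stem}_metadata.tsv"
    truth_path = out / f"{stem}_truth.json"
    samples = ds.sample_ids or [f"S{j}" for j in range(ds.n_times)]
    with open(abund_path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(samples) + "\n")
        for taxon, row in zip(ds.taxa, ds.abundance):
            fh.write(taxon + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tsource\ttime\tcondition\n")
        for s, t, c in zip(samples, ds.times, ds.conditions):
            fh.write(f"{s}\t{ds.source}\t{float(t)!r}\t{c}\n")

    def jsonable(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, tuple):
            return list(v)
        return v

    with open(truth_path, "w") as fh:
        json.dump({k: jsonable(v) for k, v in sd.truth.items()}, fh, indent=1,
                  default=str)
    return {"abundance": abund_path, "metadata": meta_path, "truth": truth_path}
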