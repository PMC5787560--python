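import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chronobiome.similarity import (
    cluster_taxa,
    default_band,
    distance_matrix,
    dtw_distance,
    pearson_matrix,
    time_dtw_distance,
)
from chronobiome.synthetic import simulate_shape_groups
from conftest import dtw_oracle, make_dataset


class TestDtwDistance:
    def test_identity_any_band(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        for band in (None, 0, 3, 25):
            assert dtw_distance(x, x, band) == 0.0

    def test_constant_offset(self):
        assert dtw_distance([0, 0, 0], [1, 1, 1]) == pytest.approx(3.0)

    def test_matches_allpaths_oracle_battery(self):
        # exhaustive warping-path enumeration on 200 random short pairs,
        # both unbanded and with a vacuously wide band
        rng = np.random.default_rng(17)
        for _ in range(200):
            x = rng.normal(size=rng.integers(1, 6))
            y = rng.normal(size=rng.integers(1, 6))
            expected = dtw_oracle(x, y)
            assert dtw_distance(x, y, None) == pytest.approx(expected, abs=1e-12)
            wide = max(len(x), len(y))
            assert dtw_distance(x, y, wide) == pytest.approx(expected, abs=1e-12)

    def test_band_widens_monotonically_to_full(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        full = dtw_distance(x, y, None)
        prev = np.inf
        for band in (0, 2, 5, 30):
            d = dtw_distance(x, y, band)
            assert d <= prev + 1e-12
            prev = d
        assert dtw_distance(x, y, 30) == pytest.approx(full)

    def test_infeasible_band(self):
        with pytest.raises(ValueError, match="band"):
            dtw_distance([1, 2, 3, 4, 5], [1], 1)

    def test_phase_shift_beats_pointwise_distance(self):
        # a one-step phase shift is cheap under warping but expensive
        # pointwise: DTW < SAD for shifted sines
        grid = np.linspace(0, 4 * np.pi, 50)
        x = np.sin(grid)
        y = np.sin(grid + (grid[1] - grid[0]))
        sad = np.abs(x - y).sum()
        assert dtw_distance(x, y) < sad


class TestTimeDtw:
    def test_identity_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        assert time_dtw_distance(x, x) == 0.0

    def test_two_point_mirror_is_exactly_one(self):
        # no warping freedom at length 2: DTW against the reflection equals
        # the SAD normalizer exactly
        x = np.array([1.0, -1.0])
        assert time_dtw_distance(x, -x) == pytest.approx(1.0, abs=1e-12)

    def test_four_point_mirror_oracle_value(self):
        # x = (1,-1,1,-1) vs its reflection: the all-paths oracle gives
        # DTW = 4 (off-diagonal alignment) against normalizer 8, i.e. 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert dtw_oracle(x, -x) == pytest.approx(4.0)
        assert time_dtw_distance(x, -x, band=None) == pytest.approx(0.5, abs=1e-12)

    def test_unit_interval_bound_battery(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            a, b = rng.normal(size=(2, 50))
            v = time_dtw_distance(a, b)
            assert 0.0 <= v <= 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=(2, 30))
            assert time_dtw_distance(a, b) == pytest.approx(
                time_dtw_distance(b, a), abs=1e-12
            )

    def test_scale_shift_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 40))
        base = time_dtw_distance(x, y)
        assert time_dtw_distance(3.7 * x + 11.0, y) == pytest.approx(base, abs=1e-9)
        assert time_dtw_distance(x, 0.01 * y - 5) == pytest.approx(base, abs=1e-9)

    def test_constant_series_rejected_by_name(self):
        with pytest.raises(ValueError, match="flatliner"):
            time_dtw_distance(
                np.ones(10), np.arange(10.0), names=("flatliner", "ramp")
            )

    def test_default_band(self):
        assert default_band(50) == 10
        assert default_band(500) == 50


class TestPearsonMatrix:
    def test_self_and_anticorrelation(self):
        x = np.arange(10.0)
        ds = make_dataset(np.vstack([x, -x]))
        dist, r = pearson_matrix(ds)
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)
        assert dist.values[0, 1] == pytest.approx(2.0)
        assert dist.values[0, 0] == 0.0

    def test_textbook_covariance_oracle(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(size=(5, 9))
        _, r = pearson_matrix(make_dataset(mat))
        for i in range(5):
            for j in range(5):
                a, b = mat[i] - mat[i].mean(), mat[j] - mat[j].mean()
                expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_taxon_flagged_missing(self):
        ds = make_dataset(np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2]))
        dist, r = pearson_matrix(ds)
        assert np.isnan(dist.values[0, 1]) and np.isnan(r[0, 2])


class TestClusterTaxa:
    def test_two_taxa_single_merge(self):
        ds = make_dataset(np.vstack([np.sin(np.linspace(0, 6, 20)),
                                     np.cos(np.linspace(0, 6, 20))]))
        dist = distance_matrix(ds, "time_dtw")
        tree = cluster_taxa(dist)
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == pytest.approx(dist.values[0, 1])

    def test_planted_shape_groups_recovered(self):
        hits = 0
        for r in range(20):
            sd = simulate_shape_groups(seed=r)
            tree = cluster_taxa(distance_matrix(sd.dataset, "time_dtw"))
            if adjusted_rand_score(sd.truth["groups"], tree.cut(2)) == 1.0:
                hits += 1
        assert hits / 20 >= 0.95

    def test_label_permutation_isomorphic(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(6, 25)))
        dist = distance_matrix(ds, "time_dtw")
        perm = rng.permutation(6)
        ds2 = make_dataset(ds.abundance[perm],
                           taxa=[ds.taxa[i] for i in perm])
        dist2 = distance_matrix(ds2, "time_dtw")
        t1, t2 = cluster_taxa(dist), cluster_taxa(dist2)
        # same merge heights and same 2/3-cuts up to label identity
        np.testing.assert_allclose(
            np.sort(t1.linkage_matrix[:, 2]), np.sort(t2.linkage_matrix[:, 2]),
            atol=1e-12,
        )
        for k in (2, 3):
            g1 = {ds.taxa[i]: c for i, c in enumerate(t1.cut(k))}
            g2 = {ds2.taxa[i]: c for i, c in enumerate(t2.cut(k))}
            part1 = {frozenset(t for t in g1 if g1[t] == c) for c in set(g1.values())}
            part2 = {frozenset(t for t in g2 if g2[t] == c) for c in set(g2.values())}
            assert part1 == part2

    def test_missing_entries_rejected(self):
        ds = make_dataset(np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)**2]))
        dist, _ = pearson_matrix(ds)
        with pytest.raises(ValueError, match="tax0"):
            cluster_taxa(dist)

    def test_newick_export_parses(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(5, 20)))
        tree = cluster_taxa(distance_matrix(ds, "time_dtw"))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4
        for t in ds.taxa:
            assert t in nwk


def test_distance_matrix_tsv_roundtrip(tmp_path):
    ds = make_dataset(np.random.default_rng(1).normal(size=(4, 15)))
    dist = distance_matrix(ds, "time_dtw")
    p = tmp_path / "d.tsv"
    dist.to_tsv(p)
    lines = p.read_text().rstrip("\n").split("\n")
    assert lines[0].split("\t")[1:] == ds.taxa
    back = np.array([[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]])
    np.testing.assert_allclose(back, dist.values)
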