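import numpy as np
import pandas as pd
import pytest

import asmb
from asmb.ddr import EARTH_RADIUS_KM, group_composites
from asmb.io import SampleMetadata


def _metadata_from_env(env: dict[str, list], group_map: dict[str, str],
                       lat=None, lon=None) -> SampleMetadata:
    n = len(next(iter(env.values())))
    df = pd.DataFrame(env, index=[f"s{i}" for i in range(n)])
    df["site_id"] = [f"S{i}" for i in range(n)]
    df["longitude"] = lon if lon is not None else np.zeros(n)
    df["latitude"] = lat if lat is not None else np.zeros(n)
    df["layer"] = "topsoil"
    return SampleMetadata(df, group_map)


class TestSpatialDistance:
    def test_one_degree_latitude(self):
        md = _metadata_from_env(
            {"ph": [7.0, 7.0]}, {"ph": "soil_ph"}, lat=[0.0, 1.0], lon=[0.0, 0.0]
        )
        d = asmb.spatial_distance(md)
        # oracle: 2*pi*R/360
        expect = 2 * np.pi * EARTH_RADIUS_KM / 360
        assert d.values[0, 1] == pytest.approx(expect, abs=0.01)
        assert d.values[0, 1] == pytest.approx(111.19, abs=0.01)

    def test_identical_points_and_symmetry(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-60, 60, 6)
        lon = rng.uniform(-150, 150, 6)
        lat[1], lon[1] = lat[0], lon[0]
        md = _metadata_from_env(
            {"ph": [7.0] * 6}, {"ph": "soil_ph"}, lat=lat, lon=lon
        )
        d = asmb.spatial_distance(md)
        assert d.values[0, 1] == 0.0
        assert np.allclose(d.values, d.values.T)


class TestEnvironmentalDistance:
    def test_identical_rows_zero(self):
        md = _metadata_from_env(
            {"ph": [7, 7, 8], "n": [1, 1, 2]},
            {"ph": "soil_ph", "n": "soil_fertility"},
        )
        d = asmb.environmental_distance(md)
        assert d.values[0, 1] == 0.0

    def test_single_group_two_sd_units(self):
        """Two sites differing only in pH: the distance equals the pH z-score
        gap, evaluated by hand with the sample (ddof=1) standard deviation."""
        ph = [6.0, 8.0, 7.0, 7.0]
        md = _metadata_from_env(
            {"ph": ph, "n": [1.0, 2.0, 3.0, 4.0]},
            {"ph": "soil_ph", "n": "soil_fertility"},
        )
        d = asmb.environmental_distance(md, ["soil_ph"])
        z = (np.array(ph) - np.mean(ph)) / np.std(ph, ddof=1)
        assert d.values[0, 1] == pytest.approx(abs(z[0] - z[1]), abs=1e-12)

    def test_constant_variable_dropped_with_warning(self):
        md = _metadata_from_env(
            {"n": [1.0, 1.0, 1.0], "c": [0.5, 1.5, 2.5]},
            {"n": "soil_fertility", "c": "soil_fertility"},
        )
        with pytest.warns(UserWarning, match="constant"):
            d = asmb.environmental_distance(md, ["soil_fertility"])
        zc = (np.array([0.5, 1.5, 2.5]) - 1.5) / 1.0
        assert d.values[0, 2] == pytest.approx(abs(zc[0] - zc[2]), abs=1e-12)

    def test_shift_invariance(self):
        env = {"mat": [1.0, 2.0, 4.0], "ph": [7.0, 8.0, 6.5]}
        gm = {"mat": "contemporary_climate", "ph": "soil_ph"}
        d1 = asmb.environmental_distance(_metadata_from_env(env, gm))
        env2 = {"mat": [x + 100 for x in env["mat"]], "ph": env["ph"]}
        d2 = asmb.environmental_distance(_metadata_from_env(env2, gm))
        assert np.allclose(d1.values, d2.values, atol=1e-12)

    def test_group_composite_is_mean_of_z_scores(self):
        env = {"a": [1.0, 3.0, 5.0], "b": [2.0, 2.5, 1.0], "ph": [7, 8, 9]}
        gm = {"a": "soil_fertility", "b": "soil_fertility", "ph": "soil_ph"}
        md = _metadata_from_env(env, gm)
        comp = group_composites(md, ["soil_fertility"])
        za = (np.array(env["a"]) - np.mean(env["a"])) / np.std(env["a"], ddof=1)
        zb = (np.array(env["b"]) - np.mean(env["b"])) / np.std(env["b"], ddof=1)
        assert np.allclose(comp["soil_fertility"], (za + zb) / 2)


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        m = asmb.PairwiseMatrix(d, [f"s{i}" for i in range(8)], "distance")
        r, p = asmb.mantel_test(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / (1 + 99))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pts1 = rng.uniform(0, 1, (8, 2))
        pts2 = rng.uniform(0, 1, (8, 2))
        labels = [f"s{i}" for i in range(8)]
        m1 = asmb.PairwiseMatrix(
            np.sqrt(((pts1[:, None] - pts1[None]) ** 2).sum(-1)), labels, "distance"
        )
        m2 = asmb.PairwiseMatrix(
            np.sqrt(((pts2[:, None] - pts2[None]) ** 2).sum(-1)), labels, "distance"
        )
        assert asmb.mantel_test(m1, m2, 199, seed=5) == asmb.mantel_test(
            m1, m2, 199, seed=5
        )


class TestDistanceDecay:
    def _linear_case(self, n=10, slope=-0.3, intercept=0.9, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.uniform(0, 1, n))
        labels = [f"s{i}" for i in range(n)]
        d = np.abs(pos[:, None] - pos[None, :])
        dist = asmb.PairwiseMatrix(d, labels, "distance")
        dz = (d - d[np.triu_indices(n, 1)].mean()) / d[np.triu_indices(n, 1)].std(
            ddof=1
        )
        sim_vals = intercept + slope * dz
        np.fill_diagonal(sim_vals, 1.0)
        sim = asmb.PairwiseMatrix(np.clip(sim_vals, 0, 1), labels, "similarity")
        return sim, dist

    def test_perfect_linear_recovery(self):
        sim, dist = self._linear_case(slope=-0.2, intercept=0.6)
        fit = asmb.fit_distance_decay(sim, dist, n_perm=99, seed=1)
        assert fit.slope == pytest.approx(-0.2, abs=1e-10)
        assert fit.intercept == pytest.approx(0.6, abs=1e-10)
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-10)
        assert fit.mantel_p == pytest.approx(1 / 100)
        assert fit.n_pairs == 45

    def test_standardization_makes_slope_scale_free(self):
        sim, dist = self._linear_case(slope=-0.25)
        doubled = asmb.PairwiseMatrix(2 * dist.values, dist.labels, "distance")
        f1 = asmb.fit_distance_decay(sim, dist, n_perm=49, seed=2)
        f2 = asmb.fit_distance_decay(sim, doubled, n_perm=49, seed=2)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-10)

    def test_shuffled_similarity_has_flat_slope(self):
        """Destroying the pairing leaves no decay on average."""
        rng = np.random.default_rng(3)
        slopes = []
        for k in range(20):
            sim, dist = self._linear_case(seed=100 + k)
            perm = rng.permutation(len(sim.labels))
            shuffled = asmb.PairwiseMatrix(
                sim.values[np.ix_(perm, perm)], sim.labels, "similarity"
            )
            fit = asmb.fit_distance_decay(shuffled, dist, n_perm=19, seed=k)
            slopes.append(fit.slope)
        assert abs(np.mean(slopes)) < 0.05

    def test_accepts_dissimilarity_input(self, small_dataset):
        table, _, md, _ = small_dataset
        top = md.subset_layer("topsoil")
        bc = asmb.bray_curtis(table.subset_samples(top.sample_ids))
        fit = asmb.fit_distance_decay(bc, asmb.spatial_distance(top), n_perm=49, seed=0)
        assert fit.n_pairs == len(top.sample_ids) * (len(top.sample_ids) - 1) // 2


class TestCompareSlopes:
    def _two_group_case(self, slope_a, slope_b, n_per_group=12, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        labels = [f"s{i}" for i in range(n)]
        grouping = pd.Series(
            ["A"] * n_per_group + ["B"] * n_per_group, index=labels
        )
        pos = rng.uniform(0, 1, n)
        d = np.abs(pos[:, None] - pos[None, :])
        dist = asmb.PairwiseMatrix(d, labels, "distance")
        du = d[np.triu_indices(n, 1)]
        dz = (d - du.mean()) / du.std(ddof=1)
        member = (np.arange(n) >= n_per_group).astype(float)
        slope = np.where(
            np.add.outer(member, member) == 2, slope_b,
            np.where(np.add.outer(member, member) == 0, slope_a, 0.5 * (slope_a + slope_b)),
        )
        sim_vals = 0.6 + slope * dz + rng.normal(0, noise, (n, n))
        sim_vals = (sim_vals + sim_vals.T) / 2
        np.fill_diagonal(sim_vals, 1.0)
        sim = asmb.PairwiseMatrix(np.clip(sim_vals, 0, 1), labels, "similarity")
        return sim, dist, grouping

    def test_equal_slopes_not_significant(self):
        sim, dist, grouping = self._two_group_case(-0.2, -0.2, seed=1)
        res = asmb.compare_slopes(sim, dist, grouping, n_perm=199, seed=2)
        assert abs(res.interaction) < 0.05
        assert res.p_permutation > 0.1

    def test_different_slopes_detected(self):
        sim, dist, grouping = self._two_group_case(-0.1, -0.4, n_per_group=30, seed=3)
        res = asmb.compare_slopes(sim, dist, grouping, n_perm=199, seed=4)
        assert res.p_permutation < 0.05
        assert res.slope_b < res.slope_a

    def test_label_swap_flips_interaction_sign(self):
        sim, dist, grouping = self._two_group_case(-0.1, -0.35, seed=5)
        swapped = grouping.map({"A": "B", "B": "A"})
        r1 = asmb.compare_slopes(sim, dist, grouping, n_perm=99, seed=6)
        r2 = asmb.compare_slopes(sim, dist, swapped, n_perm=99, seed=6)
        assert r1.interaction == pytest.approx(-r2.interaction, abs=1e-10)
        assert r1.p_permutation == pytest.approx(r2.p_permutation)

    def test_mantel_permutes_rows_and_columns_jointly(self):
        """The Mantel null must move whole samples: a joint row/column
        permutation preserves each sample's distance profile (the multiset of
        row sums), while naive independent pair shuffling destroys it."""
        rng = np.random.default_rng(7)
        n = 10
        pos = rng.uniform(0, 1, n)
        d = np.abs(pos[:, None] - pos[None, :])
        perm = rng.permutation(n)
        joint = d[np.ix_(perm, perm)]
        assert sorted(joint.sum(axis=1)) == pytest.approx(sorted(d.sum(axis=1)))
        from scipy.spatial.distance import squareform

        iu = np.triu_indices(n, 1)
        shuffled = squareform(rng.permutation(d[iu]))
        assert not np.allclose(
            sorted(shuffled.sum(axis=1)), sorted(d.sum(axis=1))
        )
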