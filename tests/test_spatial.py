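"""Geodesics, Mantel distance decay, kriging and taxon screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import skbio.stats.distance
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import microterroir as mt
from microterroir import FeatureTableError
from microterroir.spatial import EARTH_RADIUS_M

from conftest import make_table


def euclid_dm(points, ids=None) -> DistanceMatrix:
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestGeodesic:
    def test_identical_coordinates_zero(self):
        assert mt.haversine(38.0, -122.0, 38.0, -122.0) == 0.0

    def test_one_degree_latitude_at_equator(self):
        # closed form: R * pi / 180
        assert mt.haversine(0.0, 0.0, 1.0, 0.0) == pytest.approx(
            EARTH_RADIUS_M * np.pi / 180, abs=1.0)

    def test_antipodal(self):
        assert mt.haversine(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            np.pi * EARTH_RADIUS_M, abs=10.0)

    def test_matrix_properties(self, toy_metadata):
        dm = mt.geodesic_matrix(toy_metadata)
        d = dm.data
        np.testing.assert_allclose(d, d.T)
        assert np.diag(d).max() == 0.0
        # triangle inequality on random coordinate triples
        rng = np.random.default_rng(0)
        for _ in range(50):
            lat = rng.uniform(-60, 60, 3)
            lon = rng.uniform(-179, 179, 3)
            d01 = mt.haversine(lat[0], lon[0], lat[1], lon[1])
            d12 = mt.haversine(lat[1], lon[1], lat[2], lon[2])
            d02 = mt.haversine(lat[0], lon[0], lat[2], lon[2])
            assert d02 <= (d01 + d12) * (1 + 1e-6)

    def test_missing_coordinate_errors(self, toy_metadata):
        toy_metadata.data.loc["s3", "longitude"] = np.nan
        with pytest.raises(FeatureTableError, match="s3"):
            mt.geodesic_matrix(toy_metadata)


class TestProjection:
    def test_roundtrip(self):
        rng = np.random.default_rng(1)
        lat = 38.0 + rng.uniform(-0.01, 0.01, 20)
        lon = -122.0 + rng.uniform(-0.01, 0.01, 20)
        xy = mt.project_local(lat, lon, origin=(38.0, -122.0))
        back = mt.unproject_local(xy, origin=(38.0, -122.0))
        np.testing.assert_allclose(back[:, 0], lat, atol=1e-10)
        np.testing.assert_allclose(back[:, 1], lon, atol=1e-10)

    def test_planar_distance_matches_haversine_locally(self):
        xy = mt.project_local([38.0, 38.001], [-122.0, -122.001])
        planar = np.linalg.norm(xy[1] - xy[0])
        geo = mt.haversine(38.0, -122.0, 38.001, -122.001)
        assert planar == pytest.approx(geo, rel=1e-4)


def brute_force_mantel(dm_a, dm_b):
    """Exhaustive two-sided Mantel oracle via scipy.spearmanr per permutation."""
    a = np.asarray(dm_a.data)
    b = np.asarray(dm_b.data)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    obs = scipy.stats.spearmanr(a[iu], b[iu]).statistic
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        bp = b[np.ix_(perm, perm)]
        rho = scipy.stats.spearmanr(a[iu], bp[iu]).statistic
        hits += abs(rho) >= abs(obs) - 1e-12
        total += 1
    return obs, hits / total


class TestMantel:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(3)
        dm_a = euclid_dm(rng.normal(size=(6, 2)))
        dm_b = DistanceMatrix(2 * dm_a.data, ids=dm_a.ids)
        res = mt.mantel(dm_a, dm_b, n_perm=99, seed=0)
        assert res.rho == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_mode_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        dm_a = euclid_dm(rng.normal(size=(n, 2)))
        dm_b = euclid_dm(rng.normal(size=(n, 2)))
        obs, p_oracle = brute_force_mantel(dm_a, dm_b)
        res = mt.mantel(dm_a, dm_b, n_perm="exact")
        assert res.rho == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_rho_matches_skbio(self):
        rng = np.random.default_rng(8)
        dm_a = euclid_dm(rng.normal(size=(10, 2)))
        dm_b = euclid_dm(rng.normal(size=(10, 2)))
        ours = mt.mantel(dm_a, dm_b, n_perm=9, seed=0)
        ref_rho, _, _ = skbio.stats.distance.mantel(
            dm_a, dm_b, method="spearman", permutations=0)
        assert ours.rho == pytest.approx(ref_rho, abs=1e-12)

    def test_p_value_floor(self):
        rng = np.random.default_rng(3)
        dm_a = euclid_dm(rng.normal(size=(8, 2)))
        res = mt.mantel(dm_a, DistanceMatrix(dm_a.data * 3, ids=dm_a.ids),
                        n_perm=99, seed=0)
        assert res.p_value >= 1 / (res.n_permutations + 1)

    def test_mismatched_ids_error(self):
        dm_a = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        dm_b = euclid_dm(np.random.default_rng(1).normal(size=(4, 2)),
                         ids=list("wxyz"))
        with pytest.raises(FeatureTableError, match="different sample sets"):
            mt.mantel(dm_a, dm_b)

    def test_constant_distances_error(self):
        ones = 1.0 - np.eye(4)
        dm_a = DistanceMatrix(ones, ids=list("abcd"))
        dm_b = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)),
                         ids=list("abcd"))
        with pytest.raises(FeatureTableError, match="constant"):
            mt.mantel(dm_a, dm_b)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        dm_a = euclid_dm(rng.normal(size=(8, 2)))
        dm_b = euclid_dm(rng.normal(size=(8, 2)))
        r1 = mt.mantel(dm_a, dm_b, n_perm=199, seed=11)
        r2 = mt.mantel(dm_a, dm_b, n_perm=199, seed=11)
        assert (r1.rho, r1.p_value) == (r2.rho, r2.p_value)


class TestDistanceDecay:
    def test_exact_linear_input(self):
        rng = np.random.default_rng(2)
        geo = euclid_dm(rng.uniform(0, 100, size=(8, 2)))
        comm = DistanceMatrix(0.1 * (geo.data > 0) + 0.002 * geo.data,
                              ids=geo.ids)
        res = mt.distance_decay(comm, geo, n_perm=99, seed=0)
        assert res.slope == pytest.approx(0.002, abs=1e-12)
        assert res.intercept == pytest.approx(0.1, abs=1e-9)
        assert res.slope_ci[1] - res.slope_ci[0] < 1e-9
        assert len(res.pairs) == 8 * 7 // 2

    def test_constant_community_distances(self):
        rng = np.random.default_rng(2)
        geo = euclid_dm(rng.uniform(0, 100, size=(6, 2)))
        comm = DistanceMatrix(0.5 * (1 - np.eye(6)), ids=geo.ids)
        with pytest.raises(FeatureTableError, match="constant"):
            mt.distance_decay(comm, geo, n_perm=99, seed=0)
        # descriptive slope of a constant response is 0 by definition;
        # checked through the regression path with a barely varying input
        comm2 = DistanceMatrix(comm.data + 1e-15 * geo.data, ids=geo.ids)
        res = mt.distance_decay(comm2, geo, n_perm=99, seed=0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)


class TestPairClasses:
    def test_within_vineyard_pair(self):
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A", "A"], "cultivar": ["c", "c"],
            "latitude": [0.0, 0.0], "longitude": [0.0, 0.001],
            "vine": [1, 2]}, index=["s1", "s2"]))
        dm = mt.geodesic_matrix(md)
        pairs = mt.pair_class_distances(dm, md)
        assert list(pairs["pair_class"]) == ["within_vineyard"]

    def test_all_same_vine_group(self):
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A"] * 3, "cultivar": ["c"] * 3,
            "latitude": [0.0] * 3, "longitude": [0.0, 0.001, 0.002],
            "vine_group": ["OSV"] * 3}, index=["s1", "s2", "s3"]))
        pairs = mt.pair_class_distances(mt.geodesic_matrix(md), md)
        assert (pairs["pair_class"] == "within_vine").all()

    def test_combinatorial_counts(self):
        ids = [f"s{i}" for i in range(6)]
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A", "A", "B", "B", "C", "C"],
            "cultivar": ["c"] * 6,
            "latitude": np.linspace(0, 0.01, 6),
            "longitude": np.zeros(6)}, index=ids))
        pairs = mt.pair_class_distances(mt.geodesic_matrix(md), md)
        counts = pairs["pair_class"].value_counts()
        assert counts["within_vineyard"] == 3
        assert counts["between_vineyard"] == 12


class TestKriging:
    def grid(self, n_side=7, extent=90.0):
        xs, ys = np.meshgrid(np.linspace(0, extent, n_side),
                             np.linspace(0, extent, n_side))
        return np.column_stack([xs.ravel(), ys.ravel()])

    def test_constant_values_predict_constant(self):
        coords = self.grid(4)
        model = mt.fit_krige(coords, np.full(len(coords), 7.5), n_restarts=2, seed=0)
        mean, _ = model.predict([[10.0, 10.0], [200.0, 200.0]])
        np.testing.assert_allclose(mean, 7.5, atol=1e-9)

    def test_interpolates_training_points_with_pinned_noise(self):
        coords = self.grid(5)
        z = mt.sample_grf(coords, 30.0, 1.0, seed=4)
        model = mt.fit_krige(coords, z, n_restarts=3, seed=0,
                             noise_bounds=(1e-12, 1e-10))
        mean, sd = model.predict(coords)
        assert np.abs(mean - z).max() < 1e-6
        assert sd.max() < 1e-3

    def test_far_query_reverts_to_mean_and_prior_sd(self):
        coords = self.grid(5)
        rng = np.random.default_rng(0)
        z = rng.normal(3.0, 2.0, size=len(coords))
        model = mt.fit_krige(coords, z, n_restarts=3, seed=0)
        mean, sd = model.predict([[1e6, 1e6]])
        assert mean[0] == pytest.approx(z.mean(), abs=0.05 * max(1.0, abs(z.mean())))
        prior_sd = np.sqrt(model.amplitude_ + model.noise_) * model.y_std_
        assert sd[0] == pytest.approx(prior_sd, rel=0.05)

    def test_posterior_mean_interpolates_between(self):
        coords = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0],
                           [0.0, 1.0], [100.0, 1.0]])
        values = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        model = mt.fit_krige(coords, values, n_restarts=5, seed=0)
        mean, _ = model.predict([[25.0, 0.0]])
        assert 0.0 < mean[0] < 1.0

    def test_sd_grows_with_distance_from_data(self):
        coords = self.grid(5)
        z = mt.sample_grf(coords, 30.0, 1.0, seed=1)
        model = mt.fit_krige(coords, z, n_restarts=3, seed=0)
        qs = np.column_stack([np.full(5, 45.0),
                              90.0 + np.array([0.0, 20, 50, 100, 300])])
        _, sd = model.predict(qs)
        assert (np.diff(sd) >= -1e-9).all()

    def test_too_few_points_error(self):
        with pytest.raises(FeatureTableError, match=">= 5"):
            mt.fit_krige(np.zeros((4, 2)), np.zeros(4))

    def test_unfitted_predict_error(self):
        with pytest.raises(FeatureTableError, match="not fitted"):
            mt.MaternKriging().predict([[0.0, 0.0]])

    def test_trace_records_restarts(self):
        coords = self.grid(4)
        z = mt.sample_grf(coords, 20.0, 1.0, seed=2)
        model = mt.fit_krige(coords, z, n_restarts=4, seed=0)
        assert len(model.trace_) >= 3
        best = max(e.log_marginal_likelihood for e in model.trace_)
        assert model.log_marginal_likelihood_ == pytest.approx(best)


class TestTaxonScreen:
    def test_monotone_taxon_has_rho_one(self):
        n = 12
        lon = np.linspace(-122.0, -121.99, n)
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A"] * n, "cultivar": ["c"] * n,
            "latitude": np.full(n, 38.0) + np.random.default_rng(0).normal(0, 1e-5, n),
            "longitude": lon}, index=[f"s{i}" for i in range(n)]))
        counts = np.column_stack([
            np.arange(1, n + 1) * 10,          # increases in longitude
            np.full(n, 100),
            np.zeros(n, dtype=int),            # absent: filtered
        ])
        t = make_table(counts, sample_ids=[f"s{i}" for i in range(n)])
        res = mt.taxon_coordinate_screen(t, md, min_prevalence=0.5)
        res = res.set_index("feature_id")
        assert res.loc["f1", "rho_longitude"] == pytest.approx(1.0)
        assert "f3" not in res.index

    def test_bh_q_at_least_p(self):
        rng = np.random.default_rng(1)
        n = 15
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A"] * n, "cultivar": ["c"] * n,
            "latitude": 38 + rng.normal(0, 1e-4, n),
            "longitude": -122 + rng.normal(0, 1e-4, n)},
            index=[f"s{i}" for i in range(n)]))
        t = make_table(rng.integers(0, 40, size=(n, 8)),
                       sample_ids=[f"s{i}" for i in range(n)])
        res = mt.taxon_coordinate_screen(t, md, min_prevalence=0.2)
        assert (res["q_latitude"] >= res["p_latitude"] - 1e-12).all()
        assert (res["q_longitude"] >= res["p_longitude"] - 1e-12).all()

    def test_empty_screen_warns(self):
        md = mt.SampleMetadata(pd.DataFrame({
            "vineyard": ["A"] * 4, "cultivar": ["c"] * 4,
            "latitude": [38.0] * 4, "longitude": np.linspace(-122, -121.99, 4)},
            index=[f"s{i}" for i in range(4)]))
        t = make_table(np.zeros((4, 3), dtype=int),
                       sample_ids=[f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="prevalence"):
            res = mt.taxon_coordinate_screen(t, md, min_prevalence=0.5)
        assert res.empty
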