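"""Density filtration, annulus kernels, ECC curves, featurization, PCA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vineleaf.contours import Contour
from vineleaf.exceptions import DataError, DegenerateContourError, ParameterError
from vineleaf.synth import LeafGenParams, generate_leaf_contour
from vineleaf.tda import (
    FiltrationValues,
    TDAConfig,
    annulus_filter,
    average_plant_features,
    build_annuli,
    connectivity_radius,
    ecc_curve,
    feature_frame,
    featurize_leaf,
    gaussian_density,
    pca_features,
)

from conftest import brute_force_ecc, circle_points, prepare


class TestGaussianDensity:
    def test_identical_points_density_one(self):
        pts = np.zeros((7, 2))
        d = gaussian_density(pts, bandwidth=0.1)
        np.testing.assert_allclose(d.values, 1.0)

    def test_two_points_closed_form(self):
        dist, h = 0.3, 0.1
        pts = np.array([[0.0, 0.0], [dist, 0.0]])
        d = gaussian_density(pts, bandwidth=h)
        expected = (1 + np.exp(-(dist**2) / (2 * h**2))) / 2
        np.testing.assert_allclose(d.values, expected)

    def test_serration_tips_denser_than_straight_edges(self):
        # within one serrated leaf, points at serration extrema (teeth and
        # sinuses) pack neighbors closer than points on the flanks
        m = 40
        params = LeafGenParams(
            lobe_depth=0.0, serration_amp=0.15, serration_freq=m, noise_sd=0.0
        )
        raw = generate_leaf_contour(params, n_points=2000)
        theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        phase = np.abs(np.cos(m * theta))
        tips = phase > 0.9
        flanks = phase < 0.3
        dens = gaussian_density(raw, 0.02).values
        assert dens[tips].mean() > dens[flanks].mean()

    def test_invalid_bandwidth(self):
        with pytest.raises(ParameterError):
            gaussian_density(np.zeros((3, 2)), 0.0)


class TestAnnuli:
    def test_sixteen_ring_formula(self):
        part = build_annuli(16)
        assert part.radii[0] == pytest.approx(1 / 32)
        assert part.radii[-1] == pytest.approx(31 / 32)
        np.testing.assert_allclose(np.diff(part.radii), 1 / 16)
        assert part.sigma == pytest.approx(1 / 32)

    def test_single_ring_centered(self):
        part = build_annuli(1)
        assert part.radii[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [1, 4, 16, 33])
    def test_radii_increasing_below_one(self, n):
        part = build_annuli(n)
        assert np.all(np.diff(part.radii) > 0)
        assert np.all(part.radii <= 1)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            build_annuli(0)


class TestAnnulusFilter:
    def test_point_on_ring_keeps_density(self):
        part = build_annuli(16)
        pts = np.array([[part.radii[7], 0.0], [0.0, 0.0]])
        dens = gaussian_density(pts, 0.1)
        filt = annulus_filter(pts, dens, part, 8)
        assert filt.values[0] == pytest.approx(dens.values[0])

    def test_three_sigma_weight(self):
        part = build_annuli(16)
        r = part.radii[4] + 3 * part.sigma
        pts = np.array([[r, 0.0], [part.radii[4], 0.0]])
        dens = gaussian_density(pts, 10.0)  # nearly uniform density
        filt = annulus_filter(pts, dens, part, 5)
        assert filt.values[0] / dens.values[0] == pytest.approx(np.exp(-4.5), rel=1e-6)

    def test_circle_supports_outer_ring_only(self):
        contour = prepare(circle_points(500), 500)
        dens = gaussian_density(contour, 0.05)
        part = build_annuli(16)
        outer = annulus_filter(contour, dens, part, 16)
        inner = annulus_filter(contour, dens, part, 1)
        assert outer.support.all()
        assert not inner.support.any()


class TestECCCurve:
    def test_top_level_counts_max_point(self):
        pts = np.random.default_rng(0).random((30, 2))
        f = np.linspace(0.1, 1.0, 30)
        filt = FiltrationValues(values=f, support=np.ones(30, bool))
        curve = ecc_curve(pts, filt, n_thresholds=20, connectivity_eps=0.2)
        assert curve.counts[0] >= 1  # level 1 includes the max point

    def test_single_cluster_monotone_to_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 0.01, (40, 2))  # diameter << eps
        f = np.exp(-np.sum(pts**2, axis=1))  # unimodal
        filt = FiltrationValues(values=f, support=np.ones(40, bool))
        curve = ecc_curve(pts, filt, n_thresholds=30, connectivity_eps=0.5)
        assert curve.counts.max() == 1
        assert curve.counts[-1] == 1

    def test_two_separated_clusters_stay_two(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.01, (20, 2))
        b = rng.normal(0, 0.01, (20, 2)) + np.array([5.0, 0.0])
        pts = np.vstack([a, b])
        f = np.concatenate([np.full(20, 1.0), np.full(20, 1.0)]) - rng.random(40) * 0.3
        filt = FiltrationValues(values=f, support=np.ones(40, bool))
        curve = ecc_curve(pts, filt, n_thresholds=25, connectivity_eps=0.5)
        assert curve.counts[-1] == 2
        assert curve.counts.max() == 2

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(20, 200)
            pts = rng.random((n, 2))
            f = rng.random(n)
            support = f > 0.05
            eps = 0.15
            filt = FiltrationValues(values=f, support=support)
            curve = ecc_curve(pts, filt, n_thresholds=25, connectivity_eps=eps)
            oracle = brute_force_ecc(pts, f, support, curve.thresholds, eps)
            np.testing.assert_array_equal(curve.counts, oracle)

    def test_counts_lipschitz_in_insertions(self):
        # between consecutive thresholds the count changes by at most the
        # number of points inserted in that window
        rng = np.random.default_rng(7)
        pts = rng.random((150, 2))
        f = rng.random(150)
        filt = FiltrationValues(values=f, support=np.ones(150, bool))
        curve = ecc_curve(pts, filt, n_thresholds=40, connectivity_eps=0.12)
        fs = f / f.max()
        for t in range(1, len(curve.thresholds)):
            lo, hi = curve.thresholds[t], curve.thresholds[t - 1]
            inserted = int(np.sum((fs >= lo) & (fs < hi)))
            delta = int(curve.counts[t]) - int(curve.counts[t - 1])
            assert delta <= inserted  # each insertion adds at most one component
            if inserted == 0:
                assert delta == 0

    def test_empty_support_all_zero(self):
        pts = np.random.default_rng(0).random((10, 2))
        filt = FiltrationValues(values=np.zeros(10), support=np.zeros(10, bool))
        curve = ecc_curve(pts, filt, n_thresholds=10, connectivity_eps=0.1)
        assert (curve.counts == 0).all()

    def test_nonfinite_rejected(self):
        pts = np.zeros((4, 2))
        filt = FiltrationValues(values=np.array([1.0, np.nan, 0.5, 0.2]), support=np.ones(4, bool))
        with pytest.raises(DataError):
            ecc_curve(pts, filt, n_thresholds=10, connectivity_eps=0.1)


class TestFeaturizeLeaf:
    CFG = TDAConfig(n_points=300, n_thresholds=50)

    def _leaf(self, seed=0):
        params = LeafGenParams(seed=seed)
        return generate_leaf_contour(params, n_points=300)

    def test_shape_contract(self):
        vec = featurize_leaf(prepare(self._leaf().points, 300), self.CFG)
        assert vec.shape == (16 * 50,)
        assert vec.dtype.kind == "i"
        assert (vec >= 0).all()

    def test_rotation_gives_identical_vector(self):
        raw = self._leaf(3).points
        angle = np.pi / 2
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        v1 = featurize_leaf(prepare(raw, 300), self.CFG)
        v2 = featurize_leaf(prepare(raw @ rot.T, 300), self.CFG)
        np.testing.assert_array_equal(v1, v2)

    def test_circle_only_outer_rings_fire(self):
        # all mass at radius 1: rings whose kernel weight there is below the
        # support floor contribute all-zero curves
        vec = featurize_leaf(prepare(circle_points(400), 300), self.CFG)
        per_ring = vec.reshape(16, 50).sum(axis=1)
        assert per_ring[:13].sum() == 0
        assert per_ring[15] > 0

    def test_requires_normalized_contour(self):
        with pytest.raises(DataError):
            featurize_leaf(Contour(circle_points(100) * 3), self.CFG)

    def test_lobe_depth_increases_midring_mass(self):
        masses = []
        for d in (0.15, 0.3, 0.45, 0.6):
            params = LeafGenParams(lobe_depth=d, serration_amp=0.05, noise_sd=0.0)
            contour = prepare(generate_leaf_contour(params, n_points=300).points, 300)
            vec = featurize_leaf(contour, self.CFG).reshape(16, 50)
            masses.append(vec[4:12].sum())  # mid-radius rings
        assert all(a < b for a, b in zip(masses, masses[1:]))


class TestPlantAveraging:
    def test_mean_vectors(self):
        df = feature_frame(
            [
                ("l1", "v1", 2014, np.array([0, 2])),
                ("l2", "v1", 2014, np.array([2, 0])),
                ("l3", "v2", 2014, np.array([5, 5])),
            ]
        )
        out = average_plant_features(df)
        assert len(out) == 2
        np.testing.assert_allclose(
            out[out.vine_id == "v1"][["f_0001", "f_0002"]].to_numpy()[0], [1, 1]
        )

    def test_identical_vectors_mean_is_either(self):
        v = np.array([1, 2, 3])
        df = feature_frame([("l1", "v1", 2014, v), ("l2", "v1", 2014, v)])
        out = average_plant_features(df)
        np.testing.assert_allclose(out.filter(like="f_").to_numpy()[0], v)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            feature_frame(
                [("l1", "v1", 2014, np.array([1, 2])), ("l2", "v1", 2014, np.array([1]))]
            )


class TestPCA:
    def test_rank_one_data_pc1_explains_all(self):
        rng = np.random.default_rng(0)
        t = rng.random(30)
        X = np.outer(t, np.array([1.0, -2.0, 0.5]))
        df = pd.DataFrame(X, columns=["f_0001", "f_0002", "f_0003"])
        res = pca_features(df, 3)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-6)

    def test_shares_sum_to_hundred_and_decrease(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.random((40, 6)), columns=[f"f_{i:04d}" for i in range(1, 7)]
        )
        res = pca_features(df, None)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.percent_variance) <= 1e-9)
        # scores are column-centered
        scores = res.scores.filter(like="PC").to_numpy()
        np.testing.assert_allclose(scores.mean(axis=0), 0, atol=1e-9)

    def test_sign_canonicalized(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.normal(size=(50, 5)), columns=[f"f_{i:04d}" for i in range(1, 6)]
        )
        res = pca_features(df, 5)
        for _, row in res.loadings.iterrows():
            assert row.to_numpy()[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_isotropic_noise_no_dominant_component(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.normal(size=(300, 50)), columns=[f"f_{i:04d}" for i in range(1, 51)]
            )
            res = pca_features(df, None)
            mean_share = 100.0 / len(res.percent_variance)
            assert res.percent_variance[0] < 3 * mean_share

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((10, 4)), columns=[f"f_{i:04d}" for i in range(1, 5)])
        with pytest.raises(DegenerateContourError):
            pca_features(df, 2)


def test_connectivity_radius_scales_with_spacing():
    dense = circle_points(400)
    sparse = circle_points(100)
    assert connectivity_radius(sparse) > connectivity_radius(dense)
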