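"""Band-table normalization, covariance PCA, coverage ellipses, and
discriminant-band selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dggetax.fingerprint import (
    BandTable,
    BandTablePCA,
    LaneNormalizer,
    PCAResult,
    confidence_ellipse,
    group_ellipses,
    normalize_lanes,
    pca,
    select_discriminant_bands,
)
from dggetax.synthetic_data import BandTableSpec, make_band_table

from _oracles import pca_by_eigendecomposition


def _table(matrix, groups=None, lanes=None, bands=None):
    matrix = np.asarray(matrix, dtype=float)
    lanes = lanes or [f"L{i}" for i in range(matrix.shape[0])]
    bands = bands or [f"b{j}" for j in range(matrix.shape[1])]
    groups = pd.Series(groups or ["uranium"] * len(lanes), index=lanes)
    return BandTable(pd.DataFrame(matrix, index=lanes, columns=bands), groups)


class TestBandTable:
    def test_all_zero_lane_rejected_by_name(self):
        with pytest.raises(ValueError, match="L1"):
            _table([[1, 2], [0, 0], [3, 4]])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            _table([[1, -2], [3, 4], [5, 6]])

    def test_duplicate_band_ids_rejected(self):
        with pytest.raises(ValueError):
            _table([[1, 2], [3, 4], [5, 6]], bands=["b", "b"])


class TestNormalizeLanes:
    def test_example_lane(self):
        t = normalize_lanes(_table([[2, 3, 5], [1, 1, 2], [4, 0, 1]]))
        assert list(t.intensities.iloc[0]) == [20.0, 30.0, 50.0]

    def test_idempotent_on_normalized_input(self):
        t = normalize_lanes(_table([[2, 3, 5], [1, 1, 2], [4, 0, 1]]))
        again = normalize_lanes(t)
        pd.testing.assert_frame_equal(t.intensities, again.intensities)

    def test_zeros_preserved(self):
        t = normalize_lanes(_table([[0, 4], [1, 1], [2, 2]]))
        assert list(t.intensities.iloc[0]) == [0.0, 100.0]

    def test_every_lane_sums_to_100(self, rng):
        X = rng.uniform(0, 50, size=(8, 30))
        X[X < 5] = 0.0
        t = normalize_lanes(_table(X))
        np.testing.assert_allclose(t.intensities.sum(axis=1), 100.0, atol=1e-9)

    def test_estimator_wrapper(self):
        t = LaneNormalizer().transform(_table([[2, 3, 5], [1, 1, 2], [4, 0, 1]]))
        np.testing.assert_allclose(t.intensities.sum(axis=1), 100.0)


class TestPCA:
    def test_duplicate_lanes_get_identical_scores(self, rng):
        X = rng.uniform(0, 10, size=(5, 8))
        X[3] = X[1]
        p = pca(_table(X))
        np.testing.assert_allclose(
            p.scores.iloc[1].values, p.scores.iloc[3].values, atol=1e-10
        )

    def test_rank_one_table_has_pc1_at_100(self):
        X = np.ones((4, 5))
        X[:, 0] = [1, 2, 3, 4]  # variance confined to one band
        p = pca(_table(X))
        assert p.variance_fraction[0] == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Scores, loadings and variance fractions agree with a from-scratch
        covariance eigendecomposition on random 6x10 tables."""
        for _ in range(5):
            X = rng.uniform(0.1, 20, size=(6, 10))
            p = pca(_table(X))
            s_o, l_o, v_o = pca_by_eigendecomposition(X)
            k = p.scores.shape[1]
            np.testing.assert_allclose(p.scores.values, s_o[:, :k], atol=1e-8)
            np.testing.assert_allclose(p.loadings.values, l_o[:, :k], atol=1e-8)
            np.testing.assert_allclose(p.variance_fraction, v_o[:k], atol=1e-8)

    def test_variance_fractions_sum_to_100_and_decrease(self, rng):
        p = pca(_table(rng.uniform(0, 10, size=(7, 12))))
        assert p.variance_fraction.sum() == pytest.approx(100.0)
        assert all(np.diff(p.variance_fraction) <= 1e-12)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X = rng.uniform(0, 10, size=(6, 9))
        p = pca(_table(X))
        L = p.loadings.values
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        centered = X - X.mean(axis=0)
        np.testing.assert_allclose(
            p.scores.values @ L.T, centered, atol=1e-8
        )

    def test_planted_groups_separate_on_pc1(self):
        """Strong group-specific bands: PC1 score sign separates the
        uranium lanes from the controls exactly."""
        table, _ = make_band_table(
            BandTableSpec(seed=42, noise_cv=0.05, dropout=0.0)
        )
        p = pca(normalize_lanes(table))
        s = p.scores["PC1"]
        u = s[table.groups == "uranium"]
        c = s[table.groups == "control"]
        assert (u.min() > c.max()) or (c.min() > u.max())

    def test_degenerate_rank_zero_rejected(self):
        with pytest.raises(ValueError, match="rank 0|zero variance"):
            pca(_table(np.ones((4, 5))))

    def test_too_few_lanes_rejected(self):
        with pytest.raises(ValueError):
            pca(_table([[1, 2], [3, 4]]))


class TestConfidenceEllipse:
    def test_isotropic_cloud_is_near_circular(self, rng):
        pts = rng.standard_normal((10000, 2))
        e = confidence_ellipse(pts, coverage=0.90)
        assert e.semi_axes[0] / e.semi_axes[1] == pytest.approx(1.0, abs=0.05)
        assert not e.degenerate

    def test_monte_carlo_coverage_within_one_point(self, rng):
        """10,000 bivariate-normal scores: the 90% ellipse contains a
        fraction in [0.89, 0.91]."""
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=10000)
        e = confidence_ellipse(pts, coverage=0.90)
        frac = e.contains(pts).mean()
        assert 0.89 <= frac <= 0.91

    def test_collinear_points_flagged_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        e = confidence_ellipse(pts)
        assert e.degenerate

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_scaling_uses_chi_square_quantile(self, rng):
        pts = rng.standard_normal((500, 2))
        e = confidence_ellipse(pts, coverage=0.90)
        assert e.mahalanobis_radius() == pytest.approx(
            np.sqrt(stats.chi2.ppf(0.90, 2))
        )

    def test_group_ellipses_skip_small_groups(self, rng):
        X = rng.uniform(0, 10, size=(5, 6))
        groups = pd.Series(
            ["uranium"] * 3 + ["control"] * 2, index=[f"L{i}" for i in range(5)]
        )
        t = BandTable(
            pd.DataFrame(X, index=groups.index, columns=[f"b{j}" for j in range(6)]),
            groups,
        )
        p = pca(t)
        ells = group_ellipses(p, t.groups)
        assert "uranium" in ells and "control" not in ells


class TestSelectDiscriminantBands:
    def test_all_bands_sorted_by_loading(self, rng):
        p = pca(_table(rng.uniform(0, 10, size=(5, 6))))
        bands = select_discriminant_bands(p, axis=1, n=6)
        loadings = [p.loadings.loc[b, "PC1"] for b in bands]
        assert loadings == sorted(loadings, reverse=True)
        assert set(bands) == set(p.loadings.index)

    def test_planted_bands_recovered(self):
        table, truth = make_band_table(
            BandTableSpec(
                seed=7, noise_cv=0.05, dropout=0.0,
                n_specific_uranium=3, n_specific_control=0,
            )
        )
        p = pca(normalize_lanes(table))
        top3 = select_discriminant_bands(p, axis=1, n=3)
        assert set(top3) == truth["uranium"]

    def test_tie_break_by_band_id(self):
        loadings = pd.DataFrame(
            {"PC1": [0.5, 0.5, 0.5]}, index=["b_c", "b_a", "b_b"]
        )
        p = PCAResult(
            scores=pd.DataFrame(np.zeros((3, 1)), columns=["PC1"]),
            loadings=loadings,
            variance_fraction=np.array([100.0]),
        )
        assert select_discriminant_bands(p, axis=1, n=3) == ["b_a", "b_b", "b_c"]

    def test_n_too_large_rejected(self, rng):
        p = pca(_table(rng.uniform(0, 10, size=(5, 4))))
        with pytest.raises(ValueError):
            select_discriminant_bands(p, n=5)


class TestBandTablePCAEstimator:
    def test_fitted_attributes_and_bands(self):
        table, truth = make_band_table(
            BandTableSpec(seed=3, noise_cv=0.05, dropout=0.0, n_specific_control=0)
        )
        model = BandTablePCA().fit(LaneNormalizer().transform(table))
        assert model.variance_fraction_.sum() == pytest.approx(100.0)
        assert set(model.ellipses_) == {"uranium", "control"}
        assert set(model.discriminant_bands(n=6)) == truth["uranium"]

    def test_sign_convention_for_planted_uranium_bands(self):
        """With only uranium-specific bands planted, their PC1 loadings all
        come out positive under the largest-|loading|-positive convention."""
        table, truth = make_band_table(
            BandTableSpec(seed=9, noise_cv=0.05, dropout=0.0, n_specific_control=0)
        )
        p = pca(normalize_lanes(table))
        assert all(p.loadings.loc[b, "PC1"] > 0 for b in truth["uranium"])
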