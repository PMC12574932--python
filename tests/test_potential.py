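import numpy as np
import pytest
from scipy import ndimage

from agroscape.grid import Grid
from agroscape.potential import (
    PerlinParams,
    apply_hybrid,
    categorize_by_share,
    categorize_by_threshold,
    fit_hybrid,
    generate_perlin_slope,
    load_external,
    majority_smooth,
)
from oracles import morans_i


class TestPerlinSlope:
    def test_values_within_slope_range(self):
        for seed in (0, 1, 99):
            g = generate_perlin_slope(40, 40, PerlinParams(seed=seed))
            assert g.values.min() >= 0.0 and g.values.max() <= 90.0

    def test_same_seed_bit_identical(self):
        p = PerlinParams(frequency=5, octaves=4, seed=7)
        a = generate_perlin_slope(30, 50, p)
        b = generate_perlin_slope(30, 50, p)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = generate_perlin_slope(30, 30, PerlinParams(seed=1))
        b = generate_perlin_slope(30, 30, PerlinParams(seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_spatial_autocorrelation_positive(self):
        g = generate_perlin_slope(64, 64, PerlinParams(frequency=4, octaves=1, seed=42))
        assert morans_i(g.values) > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PerlinParams(octaves=0)
        with pytest.raises(ValueError):
            PerlinParams(frequency=0)


class TestCategorize:
    def test_threshold_90_marks_everything(self, slope_50):
        space = categorize_by_threshold(slope_50, 90)
        assert space.n_available == slope_50.values.size

    def test_threshold_0_marks_only_minima(self, slope_50):
        space = categorize_by_threshold(slope_50, 0)
        assert space.n_available == int((slope_50.values == 0).sum())

    def test_threshold_matches_elementwise_oracle(self, slope_50):
        space = categorize_by_threshold(slope_50, 45)
        for r in range(slope_50.nrow):
            for c in range(slope_50.ncol):
                assert space.mask.values[r, c] == (1 if slope_50.values[r, c] <= 45 else 0)

    def test_threshold_out_of_range_rejected(self, slope_50):
        with pytest.raises(ValueError):
            categorize_by_threshold(slope_50, 91)

    def test_share_one_marks_everything(self, slope_50):
        assert categorize_by_share(slope_50, 1.0).n_available == slope_50.values.size

    def test_share_half_on_distinct_values(self):
        rng = np.random.default_rng(0)
        g = Grid(rng.permutation(100).reshape(10, 10).astype(float))
        assert categorize_by_share(g, 0.5).n_available == 50

    def test_share_matches_sort_oracle(self, slope_50):
        space = categorize_by_share(slope_50, 0.7)
        k = int(np.ceil(0.7 * slope_50.values.size))
        cutoff = np.sort(slope_50.values.ravel())[k - 1]
        chosen = slope_50.values[space.mask.values == 1]
        assert space.n_available == k
        assert chosen.max() <= cutoff

    def test_share_selects_lowest_values(self, slope_50):
        space = categorize_by_share(slope_50, 0.3)
        inside = slope_50.values[space.mask.values == 1]
        outside = slope_50.values[space.mask.values == 0]
        assert inside.max() <= outside.min()

    def test_invalid_share_rejected(self, slope_50):
        with pytest.raises(ValueError):
            categorize_by_share(slope_50, 0.0)


class TestHybridFit:
    def test_intercept_only_closed_form(self):
        arable = Grid(np.array([[1, 0, 0, 0], [1, 0, 0, 0]]))
        params = fit_hybrid(arable, [])
        p = 0.25
        assert params.coefficients[0] == pytest.approx(np.log(p / (1 - p)))

    def test_informative_covariate_matches_reference_solver(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        arable_arr = (rng.random((40, 40)) < 0.4).astype(np.int8)
        cov = Grid(arable_arr + rng.normal(0, 0.2, (40, 40)))
        params = fit_hybrid(Grid(arable_arr), [cov])
        assert params.coefficients[1] > 2  # strongly positive weight

        skl = LogisticRegression(C=1e10, tol=1e-10, max_iter=1000)
        skl.fit(cov.values.ravel()[:, None], arable_arr.ravel())
        np.testing.assert_allclose(params.coefficients[1], skl.coef_[0][0], rtol=1e-3)
        np.testing.assert_allclose(params.coefficients[0], skl.intercept_[0], rtol=1e-3)
        # holdout-style accuracy of the fitted cell-wise model
        prob = 1 / (1 + np.exp(-(params.coefficients[0] + params.coefficients[1] * cov.values)))
        acc = ((prob > 0.5) == arable_arr).mean()
        assert acc > 0.95

    def test_coefficient_recovery_large_n(self):
        rng = np.random.default_rng(8)
        true = np.array([-0.5, 1.7, -1.2])
        x1, x2 = rng.normal(size=(2, 100, 100))
        eta = true[0] + true[1] * x1 + true[2] * x2
        y = (rng.random((100, 100)) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        params = fit_hybrid(Grid(y), [Grid(x1), Grid(x2)])
        assert np.abs(params.coefficients - true).max() < 0.1

    def test_null_covariate_not_significant(self):
        from scipy.stats import chi2

        def deviance(y, p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = (rng.random((20, 20)) < 0.5).astype(np.int8)
            x = Grid(rng.normal(size=(20, 20)))
            full = fit_hybrid(Grid(y), [x])
            yf = y.ravel()
            eta = full.coefficients[0] + full.coefficients[1] * x.values.ravel()
            d_full = deviance(yf, 1 / (1 + np.exp(-eta)))
            d_null = deviance(yf, np.full(yf.size, yf.mean()))
            lr = d_null - d_full
            if lr > chi2.ppf(0.95, df=1):
                rejections += 1
        assert rejections <= 10  # not significant in >= 90/100 null replicates

    def test_perfect_separation_warns_finite(self):
        y = np.zeros((10, 10), dtype=np.int8)
        y[:5] = 1
        x = Grid(y.astype(float))  # perfectly separating covariate
        with pytest.warns(RuntimeWarning):
            params = fit_hybrid(Grid(y), [x])
        assert np.isfinite(params.coefficients).all()
        assert not params.converged


class TestApplyHybrid:
    def test_certain_probabilities_give_full_mask(self):
        from agroscape.potential import HybridParams

        cov = Grid(np.ones((10, 10)))
        params = HybridParams(np.array([50.0, 0.0]), smoothing_iterations=3)
        space = apply_hybrid(params, [cov], seed=0)
        assert space.n_available == 100

    def test_zero_smoothing_equals_raw_bernoulli(self):
        from agroscape.potential import HybridParams

        cov = Grid(np.zeros((20, 20)))
        params = HybridParams(np.array([0.0, 0.0]), smoothing_iterations=0)
        space = apply_hybrid(params, [cov], seed=3)
        rng = np.random.default_rng(3)
        expected = (rng.random((20, 20)) < 0.5).astype(np.int8)
        assert np.array_equal(space.mask.values, expected)

    def test_blob_mask_covers_arable_area(self, blob_fixture):
        """Clustered potential space should exceed the arable land it was fitted to."""
        arable, covariate, _zone = blob_fixture
        params = fit_hybrid(arable, [covariate])
        wins = sum(
            apply_hybrid(params, [covariate], seed=s).n_available >= arable.values.sum()
            for s in range(100)
        )
        assert wins >= 80

    def test_shape_mismatch_rejected(self, blob_fixture):
        arable, covariate, _ = blob_fixture
        params = fit_hybrid(arable, [covariate])
        with pytest.raises(ValueError):
            apply_hybrid(params, [covariate, covariate], seed=0)


class TestMajoritySmoothing:
    def test_does_not_fragment_majority_class(self):
        """Smoothing a realization of a smooth probability surface never
        increases the 8-connected component count of the majority class."""
        s8 = np.ones((3, 3), bool)
        for seed in range(100):
            slope = generate_perlin_slope(50, 50, PerlinParams(frequency=3, seed=seed))
            prob = 1 / (1 + np.exp(-(45 - slope.values) / 8))
            rng = np.random.default_rng(seed + 1000)
            raw = (rng.random((50, 50)) < prob).astype(np.int8)
            majority = 1 if raw.mean() >= 0.5 else 0
            _, k_before = ndimage.label(raw == majority, structure=s8)
            smoothed = majority_smooth(raw, 2)
            _, k_after = ndimage.label(smoothed == majority, structure=s8)
            assert k_after <= k_before

    def test_homogeneous_region_is_fixed_point(self):
        ones = np.ones((10, 10), dtype=np.int8)
        assert np.array_equal(majority_smooth(ones, 5), ones)


class TestLoadExternal:
    def test_all_ones_valid(self):
        space = load_external(Grid(np.ones((4, 4), dtype=int)))
        assert space.provenance == "external"
        assert space.n_available == 16

    def test_non_binary_rejected_with_values(self):
        with pytest.raises(ValueError, match="2"):
            load_external(Grid(np.array([[0, 1], [2, 1]])))

    def test_thresholded_map_identity(self, slope_50):
        mask = (slope_50.values <= 30).astype(int)
        space = load_external(Grid(mask))
        assert np.array_equal(space.mask.values, mask)

    def test_nodata_becomes_unavailable(self):
        grid = Grid(np.array([[1, -9.0], [1, 0]]), nodata=-9.0)
        assert load_external(grid).n_available == 2
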