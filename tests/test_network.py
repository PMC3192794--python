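"""Structural covariance matrices and their distance dependence."""

import numpy as np
import pandas as pd
import pytest

import painmorph as pm
from painmorph.confound import CorrectedGM
from painmorph.network import DistanceFit, _pair_scatter

from conftest import holm_oracle


def _corrected(Y, groups):
    idx = [f"S{i:03d}" for i in range(len(Y))]
    data = pd.DataFrame(Y, index=idx, columns=[f"roi_{j + 1:03d}" for j in range(Y.shape[1])])
    return CorrectedGM(data=data, groups=pd.Series(groups, index=idx), covariates=[])


class TestStructuralCovariance:
    def test_symmetric_unit_diagonal_bounded(self, corrected_small):
        cov = pm.structural_covariance(corrected_small, "healthy")
        m = cov.matrix.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
        assert np.nanmax(np.abs(m)) <= 1 + 1e-12

    def test_duplicated_column_correlates_at_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 4))
        Y[:, 3] = Y[:, 0]
        cov = pm.structural_covariance(_corrected(Y, ["healthy"] * 8), "healthy")
        assert cov.matrix.iloc[0, 3] == pytest.approx(1.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 5))
        cov = pm.structural_covariance(_corrected(Y, ["CBP"] * 6), "CBP")
        for i in range(5):
            for j in range(5):
                a, b = Y[:, i], Y[:, j]
                expected = np.sum((a - a.mean()) * (b - b.mean())) / (
                    np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
                )
                assert cov.matrix.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_roi_reported_missing(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(6, 3))
        Y[:, 1] = 0.42
        with pytest.warns(UserWarning, match="zero-variance"):
            cov = pm.structural_covariance(_corrected(Y, ["OA"] * 6), "OA")
        assert cov.matrix.iloc[0, 1] != cov.matrix.iloc[0, 1]  # NaN
        assert cov.matrix.iloc[1, 1] == 1.0


class TestDistances:
    def test_three_four_five(self):
        table = pd.DataFrame(
            {
                "roi_id": [1, 2],
                "name": ["a_L", "a_R"],
                "hemisphere": ["L", "R"],
                "ba_label": ["a", "a"],
                "x_mm": [0.0, 3.0],
                "y_mm": [0.0, 4.0],
                "z_mm": [0.0, 0.0],
            }
        )
        dist = pm.pairwise_distances(pm.ROIAtlas(table))
        assert dist.iloc[0, 1] == pytest.approx(5.0)
        assert dist.iloc[0, 0] == 0.0
        assert dist.iloc[1, 0] == dist.iloc[0, 1]

    def test_translation_invariance(self, small_atlas):
        base = pm.pairwise_distances(small_atlas)
        shifted = small_atlas.table.copy()
        for c in ("x_mm", "y_mm", "z_mm"):
            shifted[c] += 10.0
        moved = pm.pairwise_distances(pm.ROIAtlas(shifted))
        np.testing.assert_allclose(base.to_numpy(), moved.to_numpy(), atol=1e-9)


class TestDistanceRegression:
    def _exact_linear_setup(self, atlas):
        # build a fake covariance whose pairwise entries follow an exact line
        dist = pm.pairwise_distances(atlas)
        cols = atlas.roi_columns
        r = 0.9 - 0.004 * dist.to_numpy()
        np.fill_diagonal(r, 1.0)
        from painmorph.network import StructuralCovariance

        cov = StructuralCovariance(
            group="healthy", matrix=pd.DataFrame(r, index=cols, columns=cols), n_subjects=20
        )
        return cov, dist

    def test_exact_line_recovered(self, small_atlas):
        cov, dist = self._exact_linear_setup(small_atlas)
        fit = pm.correlation_distance_regression(cov, dist, small_atlas, hemisphere="L")
        assert fit.slope == pytest.approx(-0.004, rel=1e-10)
        assert fit.R == pytest.approx(1.0)
        assert fit.slope_sign == -1

    def test_r_reported_as_magnitude(self, small_atlas):
        cov, dist = self._exact_linear_setup(small_atlas)
        fit = pm.correlation_distance_regression(cov, dist, small_atlas, hemisphere="L")
        assert fit.R >= 0

    def test_scatter_permutation_invariance(self, small_atlas):
        # regression is computed from the pair scatter; the scatter itself is
        # order-free, so feeding pairs in any order yields the same fit
        cov, dist = self._exact_linear_setup(small_atlas)
        d, r, _ = _pair_scatter(cov, dist, small_atlas.hemisphere_mask("L"))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(d))
        from scipy.stats import linregress

        a = linregress(d, r)
        b = linregress(d[perm], r[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.rvalue == pytest.approx(b.rvalue)

    def test_degenerate_all_equal_distances_rejected(self):
        table = pd.DataFrame(
            {
                "roi_id": [1, 2, 3, 4, 5, 6],
                "name": list("abcdef"),
                "hemisphere": ["L"] * 3 + ["R"] * 3,
                "ba_label": list("abcabc"),
                # L centroids at equilateral-triangle corners: all pair
                # distances equal within the hemisphere
                "x_mm": [-10.0, -10.0, -10.0, 10.0, 10.0, 10.0],
                "y_mm": [0.0, 12.0, 6.0, 0.0, 12.0, 6.0],
                "z_mm": [0.0, 0.0, np.sqrt(108.0), 0.0, 0.0, np.sqrt(108.0)],
            }
        )
        atlas = pm.ROIAtlas(table)
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(8, 6))
        cov = pm.structural_covariance(_corrected(Y, ["healthy"] * 8), "healthy")
        with pytest.raises(ValueError, match="degenerate"):
            pm.correlation_distance_regression(
                cov, pm.pairwise_distances(atlas), atlas, hemisphere="L"
            )


class TestCompareSlopes:
    def _fit_from_scatter(self, d, r, group="healthy"):
        from scipy.stats import linregress

        f = linregress(d, r)
        return DistanceFit(
            group=group,
            hemisphere="L",
            slope=f.slope,
            intercept=f.intercept,
            R=abs(f.rvalue),
            slope_sign=int(np.sign(f.slope)),
            p=f.pvalue,
            n_pairs=len(d),
            distances=np.asarray(d, float),
            correlations=np.asarray(r, float),
            roi_columns=["roi_001"],
        )

    def test_identical_scatters_give_zero_interaction(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(10, 150, 40)
        r = 0.8 - 0.004 * d + rng.normal(0, 0.05, 40)
        fit = self._fit_from_scatter(d, r)
        out = pm.compare_slopes(fit, self._fit_from_scatter(d, r, "CBP"))
        assert out["interaction"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_constructed_slope_difference_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(50):
            d = rng.uniform(10, 150, 100)
            ra = 0.8 - 0.004 * d + rng.normal(0, 0.03, 100)
            rb = 0.8 - 0.001 * d + rng.normal(0, 0.03, 100)
            out = pm.compare_slopes(
                self._fit_from_scatter(d, ra), self._fit_from_scatter(d, rb, "CBP")
            )
            hits += out["p"] < 0.01
        assert hits >= 45

    def test_matches_interaction_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        d1 = rng.uniform(10, 150, 30)
        d2 = rng.uniform(10, 150, 25)
        r1 = 0.7 - 0.003 * d1 + rng.normal(0, 0.05, 30)
        r2 = 0.6 - 0.001 * d2 + rng.normal(0, 0.05, 25)
        out = pm.compare_slopes(
            self._fit_from_scatter(d1, r1), self._fit_from_scatter(d2, r2, "CBP")
        )
        d = np.concatenate([d1, d2])
        g = np.r_[np.zeros(30), np.ones(25)]
        X = sm.add_constant(np.column_stack([d, g, g * d]))
        model = sm.OLS(np.concatenate([r1, r2]), X).fit()
        assert out["t"] == pytest.approx(model.tvalues[3], abs=1e-8)
        assert out["p"] == pytest.approx(model.pvalues[3], abs=1e-8)

    def test_mismatched_roi_sets_rejected(self):
        fit_a = self._fit_from_scatter([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.2, 0.1])
        fit_b = self._fit_from_scatter([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.2, 0.1])
        fit_b.roi_columns = ["roi_099"]
        with pytest.raises(ValueError, match="different ROI sets"):
            pm.compare_slopes(fit_a, fit_b)


class TestBinning:
    def test_single_occupied_bin_mean_equals_overall(self, small_atlas):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(10, small_atlas.n_rois))
        cov = pm.structural_covariance(_corrected(Y, ["healthy"] * 10), "healthy")
        dist = pm.pairwise_distances(small_atlas)
        w = float(dist.to_numpy().max()) + 1.0
        bins = pm.bin_correlations(cov, dist, bin_width_mm=w, n_bins=1)
        d, r, _ = _pair_scatter(cov, dist, None)
        assert bins.loc[0, "mean"] == pytest.approx(r.mean())
        assert bins.loc[0, "n"] == len(r)

    def test_pair_exactly_on_edge_goes_to_upper_bin(self):
        table = pd.DataFrame(
            {
                "roi_id": [1, 2],
                "name": ["a_L", "a_R"],
                "hemisphere": ["L", "R"],
                "ba_label": ["a", "a"],
                "x_mm": [-12.5, 12.5],
                "y_mm": [0.0, 0.0],
                "z_mm": [0.0, 0.0],
            }
        )
        atlas = pm.ROIAtlas(table)
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(8, 2))
        cov = pm.structural_covariance(_corrected(Y, ["healthy"] * 8), "healthy")
        bins = pm.bin_correlations(cov, pm.pairwise_distances(atlas), 25.0, 6)
        assert bins.loc[0, "n"] == 0  # pair sits at exactly 25 mm
        assert bins.loc[1, "n"] == 1

    def test_empty_bin_has_no_test(self, small_atlas):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(10, small_atlas.n_rois))
        corrected = _corrected(Y, ["healthy"] * 5 + ["CBP"] * 5)
        cov_h = pm.structural_covariance(corrected, "healthy")
        cov_p = pm.structural_covariance(corrected, "CBP")
        dist = pm.pairwise_distances(small_atlas)
        n_bins = int(np.ceil(dist.to_numpy().max() / 25.0)) + 2  # last bins empty
        bins = pm.bin_correlations(cov_p, dist, 25.0, n_bins, other=cov_h)
        empty = bins[bins["n"] == 0]
        assert not empty.empty
        assert empty["p"].isna().all()


class TestStrongConnections:
    def test_impossible_threshold_gives_empty(self, corrected_small):
        cov = pm.structural_covariance(corrected_small, "healthy")
        out = pm.strong_connections(cov, "roi_001", r_threshold=1.0)
        assert out.empty

    def test_duplicated_column_always_returned(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(10, 4))
        Y[:, 2] = Y[:, 0]
        cov = pm.structural_covariance(_corrected(Y, ["healthy"] * 10), "healthy")
        out = pm.strong_connections(cov, "roi_001", r_threshold=0.6)
        assert "roi_003" in out.index
        assert out.loc["roi_003", "r"] == pytest.approx(1.0)

    def test_adjusted_p_matches_holm_oracle(self, corrected_small):
        cov = pm.structural_covariance(corrected_small, "healthy")
        out = pm.strong_connections(cov, "roi_002", r_threshold=-1.1, alpha=1.1)
        # all pairs returned, so the family is identical; compare in place
        np.testing.assert_allclose(
            out["p_holm"], holm_oracle(out["p_raw"].to_numpy()), atol=1e-10
        )
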