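"""Winsorisation, spline mixed models, model comparison, residuals, grids."""

import numpy as np
import pandas as pd
import pytest

from natalaxis import syndata, trajectories as traj
from oracles import percentile_sort_interpolate


def _make_gene_table(n_specimens=16, seed=0, **atlas_kwargs):
    expr, truth = syndata.generate_expression_atlas(
        n_specimens=n_specimens, n_genes=1, n_planted_pos=0, n_planted_neg=0,
        seed=seed, **atlas_kwargs)
    pre = traj.preprocess_expression(expr, min_obs=5)
    return pre, truth


class TestPreprocess:
    def test_constant_vector_winsorisation_is_identity(self):
        x = np.full(30, 8.0)
        assert np.array_equal(traj.winsorize(x), x)
        assert np.allclose(traj.preprocess_gene(x), 3.0)

    def test_log2_of_eight_is_three(self):
        assert np.allclose(traj.preprocess_gene(np.array([8.0, 8, 8, 8])), 3.0)

    def test_percentiles_match_sort_and_interpolate_oracle(self):
        x = np.arange(1.0, 101.0)
        w = traj.winsorize(x, 5, 95)
        lo = percentile_sort_interpolate(x, 5)
        hi = percentile_sort_interpolate(x, 95)
        assert w.min() == pytest.approx(lo)
        assert w.max() == pytest.approx(hi)
        inner = (x >= lo) & (x <= hi)
        assert np.array_equal(w[inner], x[inner])

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError):
            traj.preprocess_gene(np.zeros(10))

    def test_pseudocount_applied_for_nonpositive_values(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        out = traj.preprocess_gene(x, lower=0, upper=100)
        assert np.isfinite(out).all()


class TestFit:
    def test_residuals_have_zero_mean(self):
        pre, _ = _make_gene_table(seed=1)
        fit = traj.fit_gene_trajectory(pre, fit_linear=False)
        resid = fit.residuals(pre)
        assert abs(resid.mean()) < 1e-6

    def test_specimen_intercepts_centred(self):
        pre, _ = _make_gene_table(seed=2, specimen_sd=0.5)
        fit = traj.fit_gene_trajectory(pre, fit_linear=False)
        b = np.array(list(fit.specimen_intercepts.values()))
        assert abs(b.mean()) < 0.05 * fit.sigma_specimen + 1e-9

    def test_nonlinear_loglik_dominates_nested_linear(self):
        for seed in range(4):
            pre, _ = _make_gene_table(seed=40 + seed)
            fit = traj.fit_gene_trajectory(pre, fit_linear=True)
            assert fit.loglik_nonlinear >= fit.loglik_linear - 1e-6

    def test_delta_bic_minus_delta_aic_identity(self):
        pre, _ = _make_gene_table(seed=5)
        fit = traj.fit_gene_trajectory(pre, fit_linear=True)
        d_aic, d_bic = traj.compare_models(fit)
        n = fit.n_obs
        delta_k = 2  # spline (4) vs intercept+linear (2), same covariates
        assert d_bic - d_aic == pytest.approx(delta_k * (np.log(n) - 2), abs=1e-8)

    def test_sex_effect_recovered_against_planted_truth(self):
        """Estimated sex coefficients track the planted per-gene values
        (Winsorisation disabled so the model is exactly well specified)."""
        expr, truth = syndata.generate_expression_atlas(
            n_specimens=16, n_genes=25, n_planted_pos=0, n_planted_neg=0,
            beta_sex_sd=0.4, specimen_sd=0.2, noise_sd=0.2,
            missing_region_rate=0.1, seed=600)
        pre = traj.preprocess_expression(expr, lower=0, upper=100, min_obs=5)
        fits = traj.fit_all_genes(pre, fit_linear=False)
        tp = truth.planted_gene_table.set_index("gene")
        est = np.array([fits[g].beta_sex for g in fits])
        true = tp.loc[list(fits), "beta_sex"].to_numpy()
        slope = np.polyfit(true, est, 1)[0]
        assert np.corrcoef(true, est)[0, 1] > 0.8
        assert 0.7 < slope < 1.3

    def test_linear_truth_prefers_linear_model_by_bic(self):
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            pre, _ = _make_gene_table(
                seed=700 + rep, traj_coef_sds=(1.0, 0.0, 0.0), noise_sd=0.4)
            fit = traj.fit_gene_trajectory(pre, fit_linear=True)
            wins += fit.bic_linear < fit.bic_nonlinear
        assert wins / n_rep > 0.5

    def test_cubic_truth_prefers_nonlinear_model_by_aic(self):
        """At high curvature-to-noise ratio the spline model wins."""
        expr, _ = syndata.generate_expression_atlas(
            n_specimens=16, n_genes=30, n_planted_pos=0, n_planted_neg=0,
            traj_coef_sds=(1.0, 1.5, 1.0), noise_sd=0.3, seed=8)
        pre = traj.preprocess_expression(expr, min_obs=5)
        fits = traj.fit_all_genes(pre, fit_linear=True)
        frac = np.mean([traj.compare_models(f)[0] < 0 for f in fits.values()])
        assert frac >= 0.9

    def test_two_specimens_minimum(self):
        pre, _ = _make_gene_table(seed=9)
        one = pre[pre.specimen_id == pre.specimen_id.iloc[0]]
        with pytest.raises(ValueError):
            traj.fit_gene_trajectory(one)


class TestResiduals:
    def test_zero_noise_null_gene_has_zero_residuals(self):
        pre, _ = _make_gene_table(
            seed=10, specimen_sd=0.0, beta_sex_sd=0.0, beta_rin_sd=0.0,
            noise_sd=0.0, missing_region_rate=0.0)
        fit = traj.fit_gene_trajectory(pre, fit_linear=False)
        fits = {pre["gene"].iloc[0]: fit}
        res = traj.age_corrected_expression(fits, pre)
        assert np.abs(res.to_numpy()).max() < 1e-6

    def test_planted_gradient_orders_region_means(self, atlas, atlas_fits,
                                                  atlas_residuals, axis_scores):
        _, truth = atlas
        planted_pos = truth.planted_gene_table.query("direction == '+'")["gene"]
        planted_pos = [g for g in planted_pos if g in atlas_residuals.columns]
        region_means = atlas_residuals[planted_pos].groupby(level="region").mean()
        mean_profile = region_means.mean(axis=1)
        r = np.corrcoef(mean_profile.to_numpy(),
                        axis_scores.reindex(mean_profile.index).to_numpy())[0, 1]
        assert r > 0.9

    def test_residuals_orthogonal_to_age(self, atlas, atlas_fits, atlas_residuals):
        pre, _ = atlas
        ages = (pre.drop_duplicates(["specimen_id", "region"])
                .set_index(["specimen_id", "region"])["age"]
                .reindex(atlas_residuals.index))
        cors = []
        for gene in atlas_residuals.columns[:30]:
            v = atlas_residuals[gene].to_numpy(float)
            ok = ~np.isnan(v)
            cors.append(np.corrcoef(v[ok], ages.to_numpy(float)[ok])[0, 1])
        assert np.mean(np.abs(cors)) < 0.05

    def test_row_order_invariance(self):
        pre, _ = _make_gene_table(seed=11)
        fit1 = traj.fit_gene_trajectory(pre, fit_linear=False)
        pre2 = pre.sample(frac=1.0, random_state=0)
        fit2 = traj.fit_gene_trajectory(pre2, fit_linear=False)
        assert np.allclose(fit1.spline_coefficients, fit2.spline_coefficients,
                           atol=1e-6)

    def test_sigma_resid_recovered(self):
        """Residual SD estimate close to the planted noise SD on average."""
        ests = []
        for rep in range(15):
            pre, _ = _make_gene_table(seed=800 + rep, noise_sd=0.5,
                                      specimen_sd=0.3)
            fit = traj.fit_gene_trajectory(pre, fit_linear=False)
            ests.append(fit.sigma_resid)
        assert abs(np.mean(ests) - 0.5) / 0.5 < 0.15


class TestRegionTrajectories:
    def test_identical_coefficient_blocks_give_identical_rows(self):
        knots = np.linspace(80.0, 260.0, 4)
        coef = np.array([1.0, 2.0, 0.5, -1.0])
        rf = traj.RegionTrajectoryFit(
            regions=["V1", "M1"], knots=knots,
            coef_blocks={"V1": coef, "M1": coef.copy()},
            beta_sex=0.1, beta_rin=0.0, rin_reference=9.0,
            age_span=(80.0, 260.0))
        grid = traj.predict_region_trajectories(rf, n_points=20)
        assert np.allclose(grid.loc["V1"], grid.loc["M1"])

    def test_two_point_grid_hits_endpoints(self):
        pre, _ = _make_gene_table(seed=12)
        rf = traj.fit_region_trajectories(pre)
        grid = traj.predict_region_trajectories(rf, window=(100.0, 200.0),
                                                n_points=2)
        assert list(grid.columns) == [100.0, 200.0]

    def test_grid_timepoints_evenly_spaced(self):
        pre, _ = _make_gene_table(seed=13)
        rf = traj.fit_region_trajectories(pre)
        grid = traj.predict_region_trajectories(rf, n_points=50)
        pts = np.asarray(grid.columns, float)
        assert len(pts) == 50
        assert np.allclose(np.diff(pts), pts[1] - pts[0], atol=1e-9)

    def test_no_extrapolation(self):
        pre, _ = _make_gene_table(seed=14)
        rf = traj.fit_region_trajectories(pre)
        with pytest.raises(ValueError):
            traj.predict_region_trajectories(rf, window=(0.0, 500.0))

    def test_planted_region_curvature_sign_recovered(self):
        """Regions with planted opposite-curvature quadratic trends keep their
        curvature sign in the fitted per-region smooths."""
        rng = np.random.default_rng(15)
        ages = np.linspace(84, 259, 14)
        rows = []
        for i, a in enumerate(ages):
            t = (a - 171.5) / 87.5
            for region, curv in (("V1", 1.0), ("M1", -1.0), ("S1", 0.5),
                                 ("A1C", -0.5)):
                mu = 4.0 + 0.5 * t + curv * t ** 2
                rows.append({"specimen_id": f"s{i}", "region": region,
                             "age": a, "sex": "F", "rin": 9.0, "gene": "g",
                             "log2": mu + rng.normal(0, 0.1)})
        tab = pd.DataFrame(rows)
        rf = traj.fit_region_trajectories(tab)
        grid = traj.predict_region_trajectories(rf, n_points=30)
        for region, curv in (("V1", 1.0), ("M1", -1.0), ("S1", 0.5), ("A1C", -0.5)):
            y = grid.loc[region].to_numpy()
            second_diff = np.diff(y, 2).mean()
            assert np.sign(second_diff) == np.sign(curv)
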