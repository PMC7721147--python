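"""Hemisphere averaging, MAD outlier removal, group PCA and projection."""

import numpy as np
import pandas as pd
import pytest

from natalaxis import imaging, syndata
from oracles import pca_svd_oracle


def _mini_table(values):
    rows = []
    for (pid, region, metric, hemi), v in values.items():
        rows.append({"participant_id": pid, "region": region, "metric": metric,
                     "hemisphere": hemi, "value": v})
    return pd.DataFrame(rows)


class TestAverageHemispheres:
    def test_arithmetic_mean(self):
        t = _mini_table({("p1", "V1", "FA", "L"): 2.0, ("p1", "V1", "FA", "R"): 4.0})
        out = imaging.average_hemispheres(t)
        assert out["value"].iloc[0] == pytest.approx(3.0)

    def test_single_hemisphere_passes_through(self):
        t = _mini_table({("p1", "V1", "FA", "L"): 1.5})
        out = imaging.average_hemispheres(t)
        assert out["value"].iloc[0] == pytest.approx(1.5)

    def test_symmetric_input_is_identity(self):
        t = _mini_table({("p1", "V1", "FA", "L"): 0.3, ("p1", "V1", "FA", "R"): 0.3,
                         ("p1", "M1", "FA", "L"): 0.4, ("p1", "M1", "FA", "R"): 0.4})
        out = imaging.average_hemispheres(t)
        assert sorted(out["value"]) == [0.3, 0.4]


class TestMadOutliers:
    def test_constant_vector_flags_nothing(self):
        assert not imaging.mad_outlier_mask(np.full(10, 3.3)).any()

    def test_single_extreme_value_flagged(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100], dtype=float)
        mask = imaging.mad_outlier_mask(x, threshold=3.5)
        # independent evaluation of the modified z-score formula
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = np.abs(0.6745 * (x - med)) / mad > 3.5
        assert np.array_equal(mask, expected)
        assert mask.sum() == 1 and mask[-1]

    def test_small_symmetric_vector_unflagged(self):
        assert not imaging.mad_outlier_mask(np.array([-1.0, 0.0, 1.0])).any()

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            imaging.mad_outlier_mask(np.array([]))


class TestGroupMatrix:
    def _table(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n):
            for r in ("V1", "M1", "S1"):
                for m in ("FA", "MD"):
                    rows.append({"participant_id": f"p{p}", "region": r,
                                 "metric": m, "value": rng.normal()})
        return pd.DataFrame(rows)

    def test_z_scores_have_zero_mean_per_metric(self):
        t = self._table()
        gm, zp = imaging.build_group_matrix(t)
        for m in ("FA", "MD"):
            vals = (t.loc[t.metric == m, "value"] - zp.loc[m, "mean"]) / zp.loc[m, "sd"]
            assert abs(vals.mean()) < 1e-12

    def test_identical_participants_average_to_either(self):
        t = self._table(n=1, seed=3)
        t2 = pd.concat([t, t.assign(participant_id="p9")], ignore_index=True)
        gm, zp = imaging.build_group_matrix(t2)
        single = t.pivot_table(index="region", columns="metric", values="value")
        z = (single - zp["mean"]) / zp["sd"]
        assert np.allclose(gm.to_numpy(), z.reindex(index=gm.index,
                                                    columns=gm.columns).to_numpy())

    def test_term_means_map_to_zero_matrix(self):
        t = self._table()
        _, zp = imaging.build_group_matrix(t)
        new = pd.DataFrame({"region": ["V1", "M1"], "metric": ["FA", "FA"],
                            "value": [zp.loc["FA", "mean"]] * 2})
        z = (new["value"] - zp.loc["FA", "mean"]) / zp.loc["FA", "sd"]
        assert np.allclose(z, 0.0)

    def test_zero_variance_metric_rejected(self):
        t = self._table()
        t.loc[t.metric == "FA", "value"] = 1.0
        with pytest.raises(ValueError):
            imaging.build_group_matrix(t)


class TestGroupPca:
    def test_rank_one_matrix_explains_everything(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([0.5, -0.5, 1.0])
        gm = pd.DataFrame(np.outer(s, w), index=list("abcd"),
                          columns=["m1", "m2", "m3"])
        axis = imaging.fit_group_pca(gm, n_components=1)
        assert axis.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one_over_full_rank(self):
        rng = np.random.default_rng(1)
        gm = pd.DataFrame(rng.normal(size=(11, 6)))
        axis = imaging.fit_group_pca(gm, n_components=6)
        assert axis.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(2)
        gm = pd.DataFrame(rng.normal(size=(11, 6)))
        axis = imaging.fit_group_pca(gm, n_components=6)
        W, evals = pca_svd_oracle(gm.to_numpy(), 6)
        assert np.allclose(axis.loadings, W, atol=1e-8)
        assert np.allclose(axis.eigenvalues, evals, atol=1e-8)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(3)
        gm = pd.DataFrame(rng.normal(size=(8, 5)))
        axis = imaging.fit_group_pca(gm, n_components=5)
        assert np.allclose(axis.loadings.T @ axis.loadings, np.eye(5), atol=1e-10)
        for j in range(5):
            k = np.argmax(np.abs(axis.loadings[:, j]))
            assert axis.loadings[k, j] > 0

    def test_region_order_invariance(self):
        rng = np.random.default_rng(4)
        gm = pd.DataFrame(rng.normal(size=(7, 4)), index=list("abcdefg"))
        axis1 = imaging.fit_group_pca(gm, n_components=2)
        perm = list("gfedcba")
        axis2 = imaging.fit_group_pca(gm.reindex(perm), n_components=2)
        s1 = pd.DataFrame(axis1.region_scores, index=axis1.regions)
        s2 = pd.DataFrame(axis2.region_scores, index=axis2.regions)
        assert np.allclose(s1.sort_index().to_numpy(), s2.sort_index().to_numpy(),
                           atol=1e-10)

    def test_rank_deficiency_rejected(self):
        gm = pd.DataFrame(np.outer([1.0, 2.0, 3.0], [1.0, 1.0]))
        with pytest.raises(ValueError):
            imaging.fit_group_pca(gm, n_components=2)


class TestProjection:
    def _axis(self, seed=0, n_components=6):
        rng = np.random.default_rng(seed)
        gm = pd.DataFrame(rng.normal(size=(11, 6)),
                          index=[f"r{i}" for i in range(11)],
                          columns=[f"m{i}" for i in range(6)])
        return imaging.fit_group_pca(gm, n_components=n_components), gm

    def test_projecting_the_group_matrix_recovers_its_scores(self):
        axis, gm = self._axis()
        sc = imaging.project_individual(gm, axis)
        assert np.allclose(sc.component_scores, axis.region_scores, atol=1e-10)

    def test_rank_one_individual_has_unit_variance_explained(self):
        axis, gm = self._axis()
        w1 = axis.loadings[:, 0]
        Xs = pd.DataFrame(np.outer(np.arange(1, 12.0), w1) + axis.column_centers,
                          index=gm.index, columns=gm.columns)
        sc = imaging.project_individual(Xs, axis)
        assert sc.variance_explained_pc1 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_individual_has_zero_variance_explained(self):
        axis, gm = self._axis()
        w2 = axis.loadings[:, 1]
        Xs = pd.DataFrame(np.outer(np.arange(1, 12.0), w2) + axis.column_centers,
                          index=gm.index, columns=gm.columns)
        sc = imaging.project_individual(Xs, axis)
        assert sc.variance_explained_pc1 == pytest.approx(0.0, abs=1e-10)

    def test_variance_explained_sums_to_one_over_full_rank(self):
        axis, gm = self._axis(seed=9)
        rng = np.random.default_rng(10)
        Xs = pd.DataFrame(rng.normal(size=(11, 6)), index=gm.index,
                          columns=gm.columns)
        sc = imaging.project_individual(Xs, axis)
        assert sc.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)

    def test_too_few_regions_rejected(self):
        axis, gm = self._axis()
        with pytest.raises(ValueError):
            imaging.project_individual(gm.iloc[:5], axis)


class TestEndToEndAxis:
    def test_planted_axis_recovered_at_low_noise(self):
        table, truth = syndata.generate_imaging_cohort(
            n_term=30, n_preterm=0, noise_sd=0.01, seed=42)
        axis, _ = imaging.compute_axis(table)
        planted = pd.Series(truth.axis_region_scores)
        r = np.corrcoef(axis.pc1_scores.reindex(planted.index), planted)[0, 1]
        assert abs(r) > 0.99

    def test_participant_order_invariance(self, imaging_cohort):
        table, _ = imaging_cohort
        term = table[table.group == "term"]
        shuffled = term.sample(frac=1.0, random_state=0)
        a1, _ = imaging.compute_axis(term)
        a2, _ = imaging.compute_axis(shuffled)
        assert np.allclose(a1.loadings, a2.loadings, atol=1e-10)
        assert np.allclose(a1.region_scores, a2.region_scores, atol=1e-10)

    def test_preterm_explains_less_variance_than_term(self, imaging_cohort):
        table, _ = imaging_cohort
        axis, _ = imaging.compute_axis(table[table.group == "term"])
        sc = imaging.project_cohort(table, axis)
        means = sc.groupby("group")["variance_explained_pc1"].mean()
        assert means["term"] > means["preterm"]
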