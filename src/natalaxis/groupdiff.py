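"""Term vs preterm comparison of regional cortical metrics.

Per metric, a linear mixed model

    value ~ age_at_scan + sex + group + PC1_score + group:PC1_score
            + (1 | participant)

is fitted by maximum likelihood; the group x score interaction tests whether
preterm effects vary along the principal axis. Nested model comparison
(with/without the birth-status terms) uses AIC/BIC from ML fits on identical
samples. Marginal group means are evaluated at pooled covariate means with
sex balanced 50/50, and Cohen's d is the marginal mean difference over the
total SD sqrt(sigma_participant^2 + sigma_resid^2). An ANCOVA compares the
per-individual variance explained by PC1 between groups, and regional
(term - preterm) metric differences are correlated with the axis scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .imaging import PrincipalAxis, average_hemispheres
from .spatial import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class MixedModelResult:
    metric: str
    coefficients: pd.DataFrame          # term, estimate, se, F, p
    aic_with_group: float
    aic_without_group: float
    bic_with_group: float
    bic_without_group: float
    marginal_means: dict[str, tuple[float, float, float]]  # group -> (mean, lo, hi)
    cohens_d: float
    sigma_participant: float
    sigma_resid: float
    loglik_with_group: float
    loglik_without_group: float
    random_effects_dropped: bool = False


def _design(df: pd.DataFrame, with_group: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df)), df["age_at_scan"].to_numpy(float),
            df["sex_num"].to_numpy(float)]
    names = ["const", "age_at_scan", "sex"]
    cols.append(df["score"].to_numpy(float))
    names.append("score_pc1")
    if with_group:
        cols.insert(3, df["is_preterm"].to_numpy(float))
        names.insert(3, "group")
        cols.append(df["is_preterm"].to_numpy(float) * df["score"].to_numpy(float))
        names.append("group:score_pc1")
    return np.column_stack(cols), names


def fit_metric_mixed_model(
    table: pd.DataFrame, axis: PrincipalAxis, metric: str
) -> MixedModelResult:
    """Fit the birth-status mixed model for one metric."""
    t = table[table["metric"] == metric].copy()
    if "hemisphere" in t.columns:
        t = average_hemispheres(t)
    if set(t["group"].unique()) != {"term", "preterm"}:
        raise ValueError("both term and preterm groups are required")
    scores = axis.pc1_scores
    missing = set(t["region"]) - set(scores.index)
    if missing:
        raise ValueError(f"regions without axis score: {sorted(missing)}")
    t["score"] = scores.reindex(t["region"]).to_numpy(float)
    t["is_preterm"] = (t["group"] == "preterm").astype(float)
    t["sex_num"] = t["sex"].map({"F": 0.0, "M": 1.0}).astype(float)

    y = t["value"].to_numpy(float)
    groups = t["participant_id"].to_numpy()

    X_full, names = _design(t, with_group=True)
    X_red, _ = _design(t, with_group=False)

    dropped_re = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res_full = sm.MixedLM(y, X_full, groups=groups).fit(reml=False, method="bfgs")
            res_red = sm.MixedLM(y, X_red, groups=groups).fit(reml=False, method="bfgs")
            sigma_b = float(np.sqrt(np.asarray(res_full.cov_re)[0, 0]))
            if not np.isfinite(sigma_b):
                raise ValueError("singular random effect")
        except Exception:
            log.warning("metric %s: singular random-effect variance; "
                        "refitting as fixed-effects", metric)
            dropped_re = True
            res_full = sm.OLS(y, X_full).fit()
            res_red = sm.OLS(y, X_red).fit()
            sigma_b = 0.0

    sigma_e = float(np.sqrt(res_full.scale)) if not dropped_re \
        else float(np.sqrt(res_full.mse_resid))

    df_resid = len(t) - X_full.shape[1]
    coef_rows = []
    params = np.asarray(res_full.params[:len(names)]) if not dropped_re \
        else np.asarray(res_full.params)
    bse = np.asarray(res_full.bse[:len(names)]) if not dropped_re \
        else np.asarray(res_full.bse)
    for i, name in enumerate(names):
        z = params[i] / bse[i]
        F = z * z
        p = float(stats.f.sf(F, 1, df_resid))
        coef_rows.append({"term": name, "estimate": float(params[i]),
                          "se": float(bse[i]), "F": float(F), "p": p})
    coefficients = pd.DataFrame(coef_rows)

    # marginal means at pooled covariate means, sex balanced, score averaged
    # over the axis regions
    age_bar = float(t["age_at_scan"].mean())
    score_bar = float(scores.reindex(axis.regions).mean())
    mm = {}
    cov = np.asarray(res_full.cov_params())[:len(names), :len(names)]
    for grp_name, g in (("term", 0.0), ("preterm", 1.0)):
        c = np.array([1.0, age_bar, 0.5, g, score_bar, g * score_bar])
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        mm[grp_name] = (est, est - 1.96 * se, est + 1.96 * se)

    total_sd = float(np.sqrt(sigma_b ** 2 + sigma_e ** 2))
    d = (mm["term"][0] - mm["preterm"][0]) / total_sd if total_sd > 0 else np.nan

    return MixedModelResult(
        metric=metric,
        coefficients=coefficients,
        aic_with_group=float(res_full.aic),
        aic_without_group=float(res_red.aic),
        bic_with_group=float(res_full.bic),
        bic_without_group=float(res_red.bic),
        marginal_means=mm,
        cohens_d=float(d),
        sigma_participant=sigma_b,
        sigma_resid=sigma_e,
        loglik_with_group=float(res_full.llf),
        loglik_without_group=float(res_red.llf),
        random_effects_dropped=dropped_re,
    )


def fit_all_metric_models(table: pd.DataFrame, axis: PrincipalAxis) -> dict[str, MixedModelResult]:
    return {m: fit_metric_mixed_model(table, axis, m)
            for m in sorted(table["metric"].unique())}


def compare_variance_explained(scores_table: pd.DataFrame) -> pd.DataFrame:
    """Type-II ANCOVA of per-individual variance explained by PC1.

    variance_explained ~ group + age_at_scan + sex + group:age_at_scan.
    `scores_table` needs columns variance_explained_pc1, group, age_at_scan,
    sex. Returns the ANOVA table (F and p per term).
    """
    t = scores_table.copy()
    if t["variance_explained_pc1"].nunique() == 1:
        raise ValueError("constant response")
    t["sex_num"] = t["sex"].map({"F": 0.0, "M": 1.0}).astype(float)
    t["grp"] = (t["group"] == "preterm").astype(float)
    model = smf.ols(
        "variance_explained_pc1 ~ grp + age_at_scan + sex_num + grp:age_at_scan",
        data=t).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={"grp": "group", "sex_num": "sex",
                                "grp:age_at_scan": "group:age_at_scan"})
    return anova


@dataclass
class GroupDifferenceProfile:
    table: pd.DataFrame        # metric, region, mean_difference
    summary: pd.DataFrame      # metric, pearson_r, p, q, degenerate flag


def regional_difference_vs_axis(
    table: pd.DataFrame, axis: PrincipalAxis
) -> GroupDifferenceProfile:
    """Correlate per-region (term - preterm) metric differences with PC1."""
    t = table
    if "hemisphere" in t.columns:
        t = average_hemispheres(t)
    scores = axis.pc1_scores
    rows, summaries = [], []
    for metric in sorted(t["metric"].unique()):
        sub = t[t["metric"] == metric]
        means = sub.pivot_table(index="region", columns="group", values="value",
                                aggfunc="mean", observed=True)
        if not {"term", "preterm"} <= set(means.columns):
            raise ValueError("both groups required")
        avail = means.dropna()
        dropped = len(means) - len(avail)
        if dropped:
            log.info("metric %s: %d region(s) dropped pairwise", metric, dropped)
        if len(avail) < 4:
            raise ValueError("need >= 4 regions with both groups")
        diff = avail["term"] - avail["preterm"]
        s = scores.reindex(diff.index).to_numpy(float)
        for region, d in diff.items():
            rows.append({"metric": metric, "region": region,
                         "mean_difference": float(d)})
        diff_scale = max(1.0, float(np.abs(diff).max()))
        if float(np.std(diff)) < 1e-12 * diff_scale or float(np.std(s)) < 1e-12:
            log.warning("metric %s: degenerate difference vector", metric)
            summaries.append({"metric": metric, "pearson_r": 0.0, "p": 1.0,
                              "degenerate": True})
            continue
        r, p = stats.pearsonr(diff.to_numpy(float), s)
        summaries.append({"metric": metric, "pearson_r": float(r),
                          "p": float(p), "degenerate": False})
    summary = pd.DataFrame(summaries)
    summary["q"] = bh_fdr(summary["p"].clip(lower=np.nextafter(0, 1)).to_numpy())
    return GroupDifferenceProfile(table=pd.DataFrame(rows), summary=summary)
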