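"""Tissue-maturity prediction from expression profiles.

Expression values are corrected for sex, RIN and specimen identity while
deliberately retaining age-related variance. A linear-kernel support vector
regression (C = 10.0) is trained leave-one-specimen-out on specimen-mean
expression vs age (postconceptional days) and predicts an age for each of the
held-out specimen's regional profiles — the region's "genetic maturity".
Bootstrap resampling of genes yields confidence intervals; the association
between regional maturity and the imaging axis is tested by permuting the
age labels of the training profiles and re-running the whole LOO pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .trajectories import TrajectoryFit, _sex_numeric

log = logging.getLogger(__name__)


def age_retained_expression(
    fits: dict[str, TrajectoryFit], table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Correct log2 expression for sex, RIN and specimen identity only.

    corrected = observed - beta_sex*sex - beta_rin*(rin - ref) - b_specimen;
    the age trend f(age) stays in. Returns (regional matrix indexed by
    (specimen_id, region), specimen-mean matrix, specimen ages in days).
    Specimens with fewer than 2 sampled regions are excluded with a warning.
    """
    cols = {}
    for gene, grp in table.groupby("gene", sort=True):
        if gene not in fits:
            continue
        f = fits[gene]
        sex = _sex_numeric(grp)
        rin = grp["rin"].to_numpy(float) - f.rin_reference
        b = grp["specimen_id"].map(f.specimen_intercepts).fillna(0.0).to_numpy(float)
        corrected = grp["log2"].to_numpy(float) - f.beta_sex * sex - f.beta_rin * rin - b
        cols[gene] = pd.Series(
            corrected,
            index=pd.MultiIndex.from_frame(grp[["specimen_id", "region"]]))
    regional = pd.DataFrame(cols).sort_index()

    counts = regional.groupby(level="specimen_id").size()
    bad = counts[counts < 2].index
    if len(bad):
        log.warning("excluding %d specimen(s) with < 2 regions: %s",
                    len(bad), list(bad))
        regional = regional.drop(index=bad, level="specimen_id")

    specimen_means = regional.groupby(level="specimen_id").mean()
    ages = (table.drop_duplicates("specimen_id").set_index("specimen_id")["age"]
            .reindex(specimen_means.index))
    return regional, specimen_means, ages


def _loo_predict(
    specimen_means: np.ndarray,
    ages: np.ndarray,
    regional: pd.DataFrame,
    specimen_ids: list[str],
    C: float = 10.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """One LOO pass; features and targets standardized with training-fold
    statistics (epsilon applies on the standardized target scale)."""
    rows = []
    reg_spec = regional.index.get_level_values("specimen_id")
    for i, sid in enumerate(specimen_ids):
        train = np.arange(len(specimen_ids)) != i
        Xtr, ytr = specimen_means[train], ages[train]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        keep = sd > 0
        if not keep.all():
            log.info("fold %s: %d constant feature(s) dropped", sid, int((~keep).sum()))
        ymu, ysd = ytr.mean(), ytr.std()
        if ysd == 0:
            raise ValueError("constant training ages")
        held = regional.loc[reg_spec == sid]
        if not keep.any():
            # no informative features: model collapses to its intercept
            pred = np.full(len(held), ymu)
        else:
            svr = SVR(kernel="linear", C=C, epsilon=epsilon)
            svr.fit((Xtr[:, keep] - mu[keep]) / sd[keep], (ytr - ymu) / ysd)
            Xte = held.to_numpy(float)[:, keep]
            pred = svr.predict((Xte - mu[keep]) / sd[keep]) * ysd + ymu
        for (_, region), p in zip(held.index, pred):
            rows.append({"specimen_id": sid, "region": region, "predicted_age": p})
    return pd.DataFrame(rows)


def loo_svr_age_prediction(
    specimen_means: pd.DataFrame,
    ages: pd.Series,
    regional: pd.DataFrame,
    C: float = 10.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Leave-one-specimen-out SVR age prediction for every regional profile."""
    if len(specimen_means) < 3:
        raise ValueError("need >= 3 specimens")
    sids = list(specimen_means.index)
    return _loo_predict(specimen_means.to_numpy(float),
                        ages.reindex(sids).to_numpy(float),
                        regional, sids, C=C, epsilon=epsilon)


def bootstrap_maturity(
    specimen_means: pd.DataFrame,
    ages: pd.Series,
    regional: pd.DataFrame,
    n_boot: int = 1000,
    C: float = 10.0,
    epsilon: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-resampling bootstrap of the LOO prediction.

    Each replicate resamples gene columns with replacement and reruns the
    full LOO pipeline. Point estimate = bootstrap mean; CI = 2.5/97.5
    percentiles.
    """
    if specimen_means.shape[1] < 10:
        raise ValueError("gene universe too small to bootstrap (need >= 10)")
    rng = np.random.default_rng(seed)
    sids = list(specimen_means.index)
    age_arr = ages.reindex(sids).to_numpy(float)
    n_genes = specimen_means.shape[1]
    reps = []
    for b in range(n_boot):
        cols = rng.integers(0, n_genes, size=n_genes)
        pred = _loo_predict(specimen_means.to_numpy(float)[:, cols], age_arr,
                            regional.iloc[:, cols], sids, C=C, epsilon=epsilon)
        pred["boot"] = b
        reps.append(pred)
    allp = pd.concat(reps, ignore_index=True)
    out = (allp.groupby(["specimen_id", "region"])
           .agg(predicted_age=("predicted_age", "mean"),
                ci_low=("predicted_age", lambda v: float(np.percentile(v, 2.5))),
                ci_high=("predicted_age", lambda v: float(np.percentile(v, 97.5))))
           .reset_index())
    out["n_boot"] = n_boot
    return out


@dataclass
class MaturityAxisResult:
    per_specimen_r: pd.Series      # specimen -> Pearson r(predicted age, axis score)
    slope: float
    r_squared: float
    permutation_p: float
    n_perm: int


def _per_specimen_correlation(predictions: pd.DataFrame,
                              axis_scores: pd.Series) -> pd.Series:
    scores = axis_scores
    if float(np.std(scores)) == 0:
        raise ValueError("degenerate axis: all region scores equal")
    rs = {}
    for sid, grp in predictions.groupby("specimen_id"):
        if len(grp) < 3:
            continue
        s = scores.reindex(grp["region"]).to_numpy(float)
        r, _ = stats.pearsonr(grp["predicted_age"].to_numpy(float), s)
        rs[sid] = r
    return pd.Series(rs)


def maturity_axis_test(
    specimen_means: pd.DataFrame,
    ages: pd.Series,
    regional: pd.DataFrame,
    axis_scores: pd.Series,
    n_perm: int = 5000,
    C: float = 10.0,
    epsilon: float = 0.1,
    seed: int = 0,
) -> MaturityAxisResult:
    """Does the maturity–axis correlation develop with specimen age?

    Observed statistic: per-specimen Pearson r between regional predicted age
    and PC1 score, regressed on specimen age; the r^2 of that fit is tested
    against a null built by permuting the training assignment of
    specimen-mean profiles to ages and re-running the whole LOO pipeline.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is small; permutation p will be unstable", n_perm)
    sids = list(specimen_means.index)
    if len(sids) < 3:
        raise ValueError("need >= 3 specimens")
    age_arr = ages.reindex(sids).to_numpy(float)

    def statistic(perm_ages: np.ndarray) -> tuple[pd.Series, float, float]:
        pred = _loo_predict(specimen_means.to_numpy(float), perm_ages,
                            regional, sids, C=C, epsilon=epsilon)
        rs = _per_specimen_correlation(pred, axis_scores)
        if len(rs) < 3:
            raise ValueError("fewer than 3 specimens with >= 3 regions")
        x = ages.reindex(rs.index).to_numpy(float)
        slope, intercept, r, _, _ = stats.linregress(x, rs.to_numpy(float))
        return rs, float(slope), float(r * r)

    per_r, slope, r2 = statistic(age_arr)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(age_arr)
        try:
            _, _, r2_null = statistic(perm)
        except ValueError:
            continue
        if r2_null >= r2:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MaturityAxisResult(per_specimen_r=per_r, slope=slope,
                              r_squared=r2, permutation_p=p, n_perm=n_perm)


def relative_regional_maturity(
    predictions: pd.DataFrame,
    ages: pd.Series,
    windows: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Centred predicted-age offsets per region and specimen-age window.

    offset = predicted age - mean predicted age within the specimen; positive
    offsets mark regions that look relatively advanced. Empty windows are
    omitted.
    """
    p = predictions.copy()
    p["offset"] = p["predicted_age"] - p.groupby("specimen_id")["predicted_age"] \
        .transform("mean")
    p["specimen_age"] = ages.reindex(p["specimen_id"]).to_numpy(float)
    if windows is None:
        lo, hi = p["specimen_age"].min(), p["specimen_age"].max() + 1e-9
        windows = [(lo, hi)]
    rows = []
    for i, (lo, hi) in enumerate(windows):
        last = i == len(windows) - 1
        mask = (p["specimen_age"] >= lo) & (
            (p["specimen_age"] <= hi) if last else (p["specimen_age"] < hi))
        sub = p[mask]
        if sub.empty:
            continue
        for region, grp in sub.groupby("region"):
            rows.append({"window": i + 1, "start": lo, "end": hi,
                         "region": region,
                         "mean_offset": float(grp["offset"].mean()),
                         "n": len(grp)})
    return pd.DataFrame(rows)
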