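"""Per-gene developmental expression trajectories.

Each gene's expression (RPKM, Winsorised and log2-transformed) is modelled as
a function of specimen age with a linear mixed-effects model,

    y ~ f(age) + beta_sex * sex + beta_rin * rin + b_specimen + eps,

where f is either a natural cubic spline with 4 knots evenly spaced across
the observed age span (nonlinear model) or a linear term (linear model), and
b_specimen is a per-specimen random intercept. Models are fitted by maximum
likelihood (not REML) so AIC/BIC comparisons across fixed-effect structures
are valid. Residuals of the nonlinear model — which contains no region terms
— retain the spatial component of expression and feed the gene–axis
association stage. A second nonlinear model with separate smooths per region
provides dense region-specific trajectory grids for the cell-type embedding
and time-window analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

log = logging.getLogger(__name__)

SEX_CODE = {"F": 0.0, "M": 1.0}


# ---------------------------------------------------------------- preprocessing

def winsorize(values: np.ndarray, lower: float = 5.0, upper: float = 95.0) -> np.ndarray:
    """Clamp values below/above the given percentiles (linear interpolation)."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.percentile(x, [lower, upper])
    return np.clip(x, lo, hi)


def preprocess_gene(values: np.ndarray, lower: float = 5.0, upper: float = 95.0) -> np.ndarray:
    """Winsorise then log2; non-positive values after clamping are shifted by
    the smallest positive clamped value as pseudocount (logged)."""
    x = winsorize(values, lower, upper)
    if np.all(x == 0):
        raise ValueError("all-zero gene")
    if (x <= 0).any():
        pseudo = x[x > 0].min()
        log.info("non-positive values after Winsorisation; adding pseudocount %g", pseudo)
        x = x + pseudo
    return np.log2(x)


def preprocess_expression(table: pd.DataFrame, lower: float = 5.0,
                          upper: float = 95.0, min_obs: int = 20) -> pd.DataFrame:
    """Add a `log2` column per gene; all-zero genes are excluded with a warning."""
    out = []
    for gene, grp in table.groupby("gene", sort=False):
        if len(grp) < min_obs:
            log.warning("gene %s has %d < %d observations; kept but flagged",
                        gene, len(grp), min_obs)
        vals = grp["rpkm"].to_numpy(dtype=float)
        if np.all(vals == 0):
            log.warning("gene %s is all-zero; excluded", gene)
            continue
        g = grp.copy()
        g["log2"] = preprocess_gene(vals, lower, upper)
        out.append(g)
    if not out:
        raise ValueError("no genes left after preprocessing")
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------------------ spline basis

def even_knots(age: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """`n_knots` knot positions evenly spaced across the observed age span."""
    return np.linspace(float(np.min(age)), float(np.max(age)), n_knots)


def spline_basis(age: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis with explicit knots (boundary knots at the
    span endpoints). Spans the intercept and linear trends, so the linear
    model is nested in the spline model."""
    b = dmatrix(
        "cr(x, knots=inner, lower_bound=lo, upper_bound=hi) - 1",
        {"x": np.asarray(age, float), "inner": knots[1:-1],
         "lo": knots[0], "hi": knots[-1]},
        return_type="matrix",
    )
    return np.asarray(b)


# ------------------------------------------------------------------------- fits

@dataclass
class RegionTrajectoryFit:
    """Region-specific smooths: one spline coefficient block per region."""

    regions: list[str]
    knots: np.ndarray
    coef_blocks: dict[str, np.ndarray]      # region -> spline coefficients
    beta_sex: float
    beta_rin: float
    rin_reference: float
    age_span: tuple[float, float]
    converged: bool = True


@dataclass
class TrajectoryFit:
    """Maximum-likelihood fit of one gene's age trajectory."""

    gene: str
    knots: np.ndarray
    spline_coefficients: np.ndarray
    beta_sex: float
    beta_rin: float
    specimen_intercepts: dict[str, float]
    sigma_resid: float
    sigma_specimen: float
    loglik_nonlinear: float
    aic_nonlinear: float
    bic_nonlinear: float
    loglik_linear: float = np.nan
    aic_linear: float = np.nan
    bic_linear: float = np.nan
    rin_reference: float = 0.0
    age_span: tuple[float, float] = (0.0, 0.0)
    n_obs: int = 0
    converged: bool = True
    region_fit: RegionTrajectoryFit | None = None

    def predict_population(self, age: np.ndarray, sex: float = 0.5,
                           rin: float | None = None) -> np.ndarray:
        """f(age) + fixed effects at reference covariates (no random effects)."""
        B = spline_basis(np.asarray(age, float), self.knots)
        rin = self.rin_reference if rin is None else rin
        return (B @ self.spline_coefficients + self.beta_sex * sex
                + self.beta_rin * (rin - self.rin_reference))

    def residuals(self, table: pd.DataFrame) -> np.ndarray:
        """Observed log2 minus (f(age) + X beta + Z b)."""
        B = spline_basis(table["age"].to_numpy(float), self.knots)
        sex = _sex_numeric(table)
        rin = table["rin"].to_numpy(float) - self.rin_reference
        fitted = (B @ self.spline_coefficients + self.beta_sex * sex
                  + self.beta_rin * rin)
        b = table["specimen_id"].map(self.specimen_intercepts).fillna(0.0).to_numpy(float)
        return table["log2"].to_numpy(float) - fitted - b


def _sex_numeric(table: pd.DataFrame) -> np.ndarray:
    s = table["sex"]
    if s.dtype == object:
        return s.map(SEX_CODE).to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def _fit_mixed(y, X, groups):
    """ML mixed fit with a random intercept; retries with a second optimizer
    on non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=False, method="bfgs", maxiter=500)
            if res.converged:
                return res, True
        except Exception:
            pass
        try:
            res = model.fit(reml=False, maxiter=1000)
            if res.converged:
                return res, True
        except Exception:
            pass
        res = model.fit(reml=False, method="powell", maxiter=1000)
        return res, bool(res.converged)


def _random_intercepts(res) -> dict[str, float]:
    """Predicted specimen intercepts; zeros when the random-effect variance
    collapsed to the boundary (then the fit is effectively fixed-effects)."""
    try:
        return {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
    except Exception:
        return {}


def fit_gene_trajectory(
    gene_table: pd.DataFrame,
    n_knots: int = 4,
    fit_linear: bool = True,
    fit_region: bool = False,
) -> TrajectoryFit:
    """Fit nonlinear (spline) and linear age models for one gene.

    `gene_table` must carry columns specimen_id, region, age, sex, rin, log2.
    Rows are canonicalised (sorted by specimen and region) before fitting so
    the result does not depend on input row order.
    """
    t = gene_table.sort_values(["specimen_id", "region"], kind="mergesort")
    age = t["age"].to_numpy(float)
    if t["specimen_id"].nunique() < 2:
        raise ValueError("need >= 2 specimens")
    if np.ptp(age) <= 0:
        raise ValueError("age span must be positive")
    y = t["log2"].to_numpy(float)
    sex = _sex_numeric(t)
    rin_ref = float(t["rin"].mean())
    rin = t["rin"].to_numpy(float) - rin_ref
    groups = t["specimen_id"].to_numpy()

    # constant covariates carry no information and would make the design
    # singular; drop them with a zero coefficient
    use_sex = np.ptp(sex) > 0
    use_rin = np.ptp(rin) > 0

    knots = even_knots(age, n_knots)
    B = spline_basis(age, knots)
    cols = [B] + ([sex] if use_sex else []) + ([rin] if use_rin else [])
    X_nl = np.column_stack(cols)
    res_nl, conv_nl = _fit_mixed(y, X_nl, groups)

    k = B.shape[1]
    re = _random_intercepts(res_nl)
    j = k
    beta_sex = float(res_nl.fe_params[j]) if use_sex else 0.0
    j += int(use_sex)
    beta_rin = float(res_nl.fe_params[j]) if use_rin else 0.0
    fit = TrajectoryFit(
        gene=str(t["gene"].iloc[0]) if "gene" in t.columns else "",
        knots=knots,
        spline_coefficients=np.asarray(res_nl.fe_params[:k]),
        beta_sex=beta_sex,
        beta_rin=beta_rin,
        specimen_intercepts=re,
        sigma_resid=float(np.sqrt(res_nl.scale)),
        sigma_specimen=float(np.sqrt(np.asarray(res_nl.cov_re)[0, 0])),
        loglik_nonlinear=float(res_nl.llf),
        aic_nonlinear=float(res_nl.aic),
        bic_nonlinear=float(res_nl.bic),
        rin_reference=rin_ref,
        age_span=(float(age.min()), float(age.max())),
        n_obs=len(t),
        converged=conv_nl,
    )

    if fit_linear:
        lin_cols = [np.ones_like(age), age] + ([sex] if use_sex else []) \
            + ([rin] if use_rin else [])
        X_lin = np.column_stack(lin_cols)
        res_lin, conv_lin = _fit_mixed(y, X_lin, groups)
        fit.loglik_linear = float(res_lin.llf)
        fit.aic_linear = float(res_lin.aic)
        fit.bic_linear = float(res_lin.bic)
        fit.converged = fit.converged and conv_lin

    if fit_region:
        fit.region_fit = fit_region_trajectories(t, n_knots=n_knots)
    return fit


def fit_region_trajectories(gene_table: pd.DataFrame, n_knots: int = 4) -> RegionTrajectoryFit:
    """Nonlinear model with a separate smooth per cortical region."""
    t = gene_table.sort_values(["specimen_id", "region"], kind="mergesort")
    age = t["age"].to_numpy(float)
    knots = even_knots(age, n_knots)
    B = spline_basis(age, knots)
    regions = sorted(t["region"].unique())
    blocks = []
    for r in regions:
        ind = (t["region"] == r).to_numpy(float)[:, None]
        blocks.append(B * ind)
    sex = _sex_numeric(t)
    rin_ref = float(t["rin"].mean())
    rin = t["rin"].to_numpy(float) - rin_ref
    use_sex = np.ptp(sex) > 0
    use_rin = np.ptp(rin) > 0
    cols = blocks + ([sex] if use_sex else []) + ([rin] if use_rin else [])
    X = np.column_stack(cols)
    res, conv = _fit_mixed(t["log2"].to_numpy(float), X, t["specimen_id"].to_numpy())
    k = B.shape[1]
    coef_blocks = {
        r: np.asarray(res.fe_params[i * k:(i + 1) * k]) for i, r in enumerate(regions)
    }
    j = len(regions) * k
    beta_sex = float(res.fe_params[j]) if use_sex else 0.0
    j += int(use_sex)
    beta_rin = float(res.fe_params[j]) if use_rin else 0.0
    return RegionTrajectoryFit(
        regions=regions, knots=knots, coef_blocks=coef_blocks,
        beta_sex=beta_sex, beta_rin=beta_rin,
        rin_reference=rin_ref,
        age_span=(float(age.min()), float(age.max())),
        converged=conv,
    )


def compare_models(fit: TrajectoryFit) -> tuple[float, float]:
    """(delta AIC, delta BIC), nonlinear minus linear; negative favours the
    nonlinear model."""
    if np.isnan(fit.aic_linear):
        raise ValueError("linear model was not fitted")
    return (fit.aic_nonlinear - fit.aic_linear, fit.bic_nonlinear - fit.bic_linear)


def fit_all_genes(
    table: pd.DataFrame,
    n_knots: int = 4,
    fit_linear: bool = False,
    fit_region: bool = False,
    genes: list[str] | None = None,
) -> dict[str, TrajectoryFit]:
    """Fit every gene (or a subset); non-convergent genes are excluded with a
    logged warning."""
    fits: dict[str, TrajectoryFit] = {}
    for gene, grp in table.groupby("gene", sort=True):
        if genes is not None and gene not in genes:
            continue
        try:
            f = fit_gene_trajectory(grp, n_knots=n_knots, fit_linear=fit_linear,
                                    fit_region=fit_region)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("gene %s failed to fit (%s); excluded", gene, exc)
            continue
        if not f.converged:
            log.warning("gene %s did not converge; excluded", gene)
            continue
        fits[gene] = f
    return fits


def age_corrected_expression(
    fits: dict[str, TrajectoryFit], table: pd.DataFrame
) -> pd.DataFrame:
    """Residual matrix (sample x gene) of the nonlinear, region-agnostic model.

    The model includes no region term, so regional signal remains in the
    residuals. Rows indexed by (specimen_id, region)."""
    cols = {}
    needed = ["specimen_id", "region", "age", "sex", "rin", "log2"]
    for gene, grp in table.groupby("gene", sort=True):
        if gene not in fits:
            continue
        g = grp.dropna(subset=[c for c in needed if c in grp.columns])
        if len(g) < len(grp):
            log.info("gene %s: %d sample(s) dropped for missing covariates",
                     gene, len(grp) - len(g))
        resid = fits[gene].residuals(g)
        cols[gene] = pd.Series(
            resid, index=pd.MultiIndex.from_frame(
                g[["specimen_id", "region"]], names=["specimen_id", "region"]))
    out = pd.DataFrame(cols)
    out = out.sort_index()
    return out


def predict_region_trajectories(
    region_fit: RegionTrajectoryFit,
    window: tuple[float, float] | None = None,
    n_points: int = 50,
    sex: float = 0.5,
) -> pd.DataFrame:
    """Evaluate each region's smooth at `n_points` evenly spaced ages.

    Fixed effects are evaluated at reference covariates (sex balanced at 0.5,
    RIN at the sample mean). No extrapolation outside the fitted span.
    Returns a region x timepoint DataFrame (columns are ages in days).
    """
    lo, hi = window if window is not None else region_fit.age_span
    if lo < region_fit.age_span[0] - 1e-9 or hi > region_fit.age_span[1] + 1e-9:
        raise ValueError(f"window ({lo}, {hi}) outside fitted span "
                         f"{region_fit.age_span}; no extrapolation")
    ages = np.linspace(lo, hi, n_points)
    B = spline_basis(ages, region_fit.knots)
    rows = {r: B @ region_fit.coef_blocks[r] + region_fit.beta_sex * sex
            for r in region_fit.regions}
    return pd.DataFrame(rows, index=ages).T


def trajectory_grids(
    fits: dict[str, TrajectoryFit],
    window: tuple[float, float],
    n_points: int = 50,
) -> pd.DataFrame:
    """Long-format grid over genes with region fits: columns gene, region,
    age, predicted_log2."""
    frames = []
    for gene, fit in fits.items():
        if fit.region_fit is None:
            continue
        g = predict_region_trajectories(fit.region_fit, window, n_points)
        long = g.reset_index(names="region").melt(
            id_vars="region", var_name="age", value_name="predicted_log2")
        long.insert(0, "gene", gene)
        frames.append(long)
    if not frames:
        raise ValueError("no region fits available")
    out = pd.concat(frames, ignore_index=True)
    out["age"] = out["age"].astype(float)
    return out
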