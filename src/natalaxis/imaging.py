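"""Principal axis of regional cortical MRI metrics.

Pipeline: average metric values across hemispheres, remove extreme values by
modified z-score (median absolute deviation), z-score each metric over the
pooled term-cohort observations, average within region to a group
region x metric matrix, and extract principal axes by eigendecomposition of
its covariance. Individual participants (term or preterm) are then projected
onto the group axes with the frozen z-scaling, yielding per-individual
component scores and the fraction of their (centred) matrix energy explained
by the first component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Iglewicz–Hoaglin consistency constant relating MAD to the normal SD.
MAD_CONSISTENCY = 0.6745


@dataclass
class PrincipalAxis:
    """Group principal axes: loadings over metrics, scores over regions."""

    metrics: list[str]
    regions: list[str]
    metric_means: np.ndarray        # term-cohort z-scaling, per metric
    metric_sds: np.ndarray
    column_centers: np.ndarray      # group-matrix column means, per metric
    loadings: np.ndarray            # metric x component (orthonormal columns)
    region_scores: np.ndarray       # region x component
    variance_fraction: np.ndarray   # per component
    eigenvalues: np.ndarray

    @property
    def pc1_scores(self) -> pd.Series:
        return pd.Series(self.region_scores[:, 0], index=self.regions, name="PC1")

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.region_scores.shape[1])]
        return pd.DataFrame(self.region_scores, index=self.regions, columns=cols)


@dataclass
class AxisScores:
    """Per-participant projections onto the group axes."""

    participant_id: str
    regions: list[str]
    component_scores: np.ndarray    # region x component
    variance_explained: np.ndarray  # per component, of the centred matrix
    n_regions_used: int = 0

    @property
    def variance_explained_pc1(self) -> float:
        return float(self.variance_explained[0])


def average_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Average metric values across hemispheres.

    Entries present in a single hemisphere pass through as that value (with a
    logged warning); entries missing in both hemispheres are absent from the
    output.
    """
    if "hemisphere" not in table.columns:
        raise ValueError("table has no hemisphere column")
    keys = [c for c in table.columns if c not in ("hemisphere", "value")]
    counts = table.groupby(keys, sort=False, observed=True)["value"].count()
    n_single = int((counts == 1).sum())
    if n_single:
        log.warning("%d (participant, region, metric) entries present in one "
                    "hemisphere only; passed through unaveraged", n_single)
    out = (table.groupby(keys, sort=False, observed=True, as_index=False)["value"]
           .mean())
    return out


def mad_outlier_mask(values: np.ndarray, threshold: float = 3.5) -> np.ndarray:
    """Boolean mask of values whose modified z-score exceeds `threshold`.

    Modified z = 0.6745 * (x - median) / MAD with MAD the median absolute
    deviation. A zero MAD (degenerate spread) flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(x.shape, dtype=bool)
    return np.abs(MAD_CONSISTENCY * (x - med)) / mad > threshold


def remove_outliers_mad(table: pd.DataFrame, threshold: float = 3.5) -> pd.DataFrame:
    """Drop outlying values per (region, metric) across participants."""
    masks = []
    for _, grp in table.groupby(["region", "metric"], sort=False, observed=True):
        if len(grp) < 3:
            raise ValueError("need >= 3 observations per (region, metric)")
        flagged = mad_outlier_mask(grp["value"].to_numpy(), threshold)
        masks.append(pd.Series(flagged, index=grp.index))
    mask = pd.concat(masks).reindex(table.index)
    n = int(mask.sum())
    if n:
        log.info("removed %d outlying values (MAD threshold %.2f)", n, threshold)
    return table.loc[~mask].copy()


def build_group_matrix(
    term_table: pd.DataFrame,
    regions: list[str] | None = None,
    metrics: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score per metric over pooled term observations; average per region.

    Returns the group region x metric matrix and the frozen z-parameters
    (term-cohort mean and SD per metric) used to place any individual —
    including preterm infants — on the same scale.
    """
    t = term_table
    if "group" in t.columns and not (t["group"] == "term").all():
        raise ValueError("group matrix must be built from the term cohort only")
    regions = regions or sorted(t["region"].unique())
    metrics = metrics or sorted(t["metric"].unique())

    zparams = {}
    zcols = {}
    for m in metrics:
        vals = t.loc[t["metric"] == m, "value"]
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"zero variance in metric {m!r}")
        zparams[m] = (mu, sd)
    zp = pd.DataFrame(zparams, index=["mean", "sd"]).T

    z = t.copy()
    z["value"] = (z["value"] - z["metric"].map(zp["mean"]).astype(float)) / \
        z["metric"].map(zp["sd"]).astype(float)
    counts = z.groupby(["region", "metric"], observed=True)["value"].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 participants per (region, metric)")
    gm = (z.pivot_table(index="region", columns="metric", values="value",
                        aggfunc="mean", observed=True)
          .reindex(index=regions, columns=metrics))
    if gm.isna().any().any():
        raise ValueError("missing (region, metric) cells in group matrix")
    return gm, zp


def fit_group_pca(group_matrix: pd.DataFrame, n_components: int = 2) -> PrincipalAxis:
    """Eigendecomposition of the covariance of the region x metric matrix.

    Columns (metrics) are centred; eigenvectors of the metric x metric
    covariance give the loadings; region scores are the centred matrix times
    the loadings; variance fractions are eigenvalues over the trace. Sign
    convention: the loading of maximal magnitude in each component is
    positive.
    """
    X = group_matrix.to_numpy(dtype=float)
    n_r, n_m = X.shape
    if n_r < 2:
        raise ValueError("need >= 2 regions")
    centers = X.mean(axis=0)
    Xc = X - centers
    cov = Xc.T @ Xc / (n_r - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")

    # sign convention
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]

    W = evecs[:, :n_components]
    T = Xc @ W
    total = evals.sum()
    vf = evals[:n_components] / total if total > 0 else np.zeros(n_components)
    return PrincipalAxis(
        metrics=list(group_matrix.columns),
        regions=list(group_matrix.index),
        metric_means=np.full(n_m, np.nan),
        metric_sds=np.full(n_m, np.nan),
        column_centers=centers,
        loadings=W,
        region_scores=T,
        variance_fraction=vf,
        eigenvalues=evals[:n_components],
    )


def compute_axis(
    term_table: pd.DataFrame,
    n_components: int = 2,
    mad_threshold: float = 3.5,
    regions: list[str] | None = None,
    metrics: list[str] | None = None,
) -> tuple[PrincipalAxis, pd.DataFrame]:
    """Full term-cohort axis: hemisphere average -> MAD QC -> z -> PCA.

    Returns the fitted axis (with frozen z-parameters attached) and the
    z-parameter table.
    """
    t = term_table[term_table["group"] == "term"] if "group" in term_table.columns \
        else term_table
    if "hemisphere" in t.columns:
        t = average_hemispheres(t)
    t = remove_outliers_mad(t, mad_threshold)
    gm, zp = build_group_matrix(t, regions=regions, metrics=metrics)
    axis = fit_group_pca(gm, n_components=n_components)
    axis.metric_means = zp["mean"].reindex(axis.metrics).to_numpy()
    axis.metric_sds = zp["sd"].reindex(axis.metrics).to_numpy()
    return axis, zp


def participant_matrix(
    table: pd.DataFrame, participant_id: str, axis: PrincipalAxis
) -> pd.DataFrame:
    """One participant's region x metric matrix on the frozen term z-scale."""
    t = table[table["participant_id"] == participant_id]
    if "hemisphere" in t.columns:
        t = average_hemispheres(t)
    mat = t.pivot_table(index="region", columns="metric", values="value",
                        observed=True)
    mat = mat.reindex(columns=axis.metrics)
    mat = (mat - axis.metric_means) / axis.metric_sds
    return mat.reindex(index=[r for r in axis.regions if r in mat.index])


def project_individual(matrix: pd.DataFrame, axis: PrincipalAxis,
                       participant_id: str = "") -> AxisScores:
    """Project a z-scored individual matrix onto the group axes.

    Rows are centred with the group column centres; scores are X_s W and the
    per-component variance explained is ||X~ w_j||^2 / ||X~||_F^2.
    """
    avail = matrix.dropna(axis=0, how="any")
    n_missing = len(matrix) - len(avail)
    if n_missing:
        log.info("participant %s: %d region(s) missing, projecting on %d",
                 participant_id, n_missing, len(avail))
    if len(avail) < 6:
        raise ValueError("fewer than 6 regions available for projection")
    X = avail.to_numpy(dtype=float)
    Xc = X - axis.column_centers
    T = Xc @ axis.loadings
    denom = float(np.sum(Xc ** 2))
    if denom == 0:
        ve = np.zeros(axis.loadings.shape[1])
    else:
        ve = np.sum(T ** 2, axis=0) / denom
    return AxisScores(
        participant_id=participant_id,
        regions=list(avail.index),
        component_scores=T,
        variance_explained=ve,
        n_regions_used=len(avail),
    )


def project_cohort(table: pd.DataFrame, axis: PrincipalAxis) -> pd.DataFrame:
    """Project every participant; returns one row per participant with
    variance explained by PC1 and participant metadata."""
    meta_cols = [c for c in ("group", "age_at_scan", "age_at_birth", "sex")
                 if c in table.columns]
    rows = []
    for pid, grp in table.groupby("participant_id", sort=True):
        mat = participant_matrix(grp, pid, axis)
        sc = project_individual(mat, axis, participant_id=pid)
        row = {"participant_id": pid,
               "variance_explained_pc1": sc.variance_explained_pc1,
               "n_regions_used": sc.n_regions_used}
        for c in meta_cols:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
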