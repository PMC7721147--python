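"""Synthetic imaging cohorts, expression atlases, gene-set catalogs and DE lists.

Every generator plants a recorded ground truth (:class:`SyntheticTruth`) so the
downstream estimators — principal-axis recovery, gene–axis association,
cell-class enrichment, maturity prediction, group comparison — can be tested
without access to restricted cohort data. Generation starts at the
region-level summary tables; no raw images or reads are simulated.

The imaging generator composes each observation as a shared rank-1
axis (participant weight x region score x metric loading) plus group effects
aligned to the axis, an age-at-scan trend, and hemispheric noise. The
expression generator produces log2-scale signals from cubic age trajectories
with specimen random intercepts, sex/RIN nuisance effects and, for planted
genes, a spatial gradient proportional to the region score. Cubic
trajectories are exactly representable by the 4-knot natural cubic spline
fitted downstream, so recovery tests run under a well-specified model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import (
    DEFAULT_CELL_CLASSES,
    DEFAULT_REGION_SCORES,
    METRICS,
    REGIONS,
)

# Metric-native means and scales (native units per z-like unit of simulated
# effect): thickness in mm, MD in um^2/ms, the rest dimensionless ratios.
DEFAULT_METRIC_MEANS: dict[str, float] = {
    "thickness": 1.30, "t1t2": 1.32, "FA": 0.15,
    "MD": 1.15, "fICVF": 0.45, "ODI": 0.35,
}
DEFAULT_METRIC_SCALES: dict[str, float] = {
    "thickness": 0.08, "t1t2": 0.06, "FA": 0.02,
    "MD": 0.05, "fICVF": 0.04, "ODI": 0.03,
}

# Unit-norm loading pattern: MD varies opposite to the myelination-sensitive
# metrics along the axis.
_RAW_LOADINGS = {
    "thickness": 0.30, "t1t2": 0.55, "FA": 0.35,
    "MD": -0.50, "fICVF": 0.45, "ODI": 0.18,
}
_NORM = float(np.sqrt(sum(v * v for v in _RAW_LOADINGS.values())))
DEFAULT_METRIC_LOADINGS: dict[str, float] = {k: v / _NORM for k, v in _RAW_LOADINGS.items()}

# Preterm-minus-term effects in scale units: lower t1t2/fICVF/FA, higher MD
# and thickness (magnitudes sized to give Cohen's d of roughly 1.6, 1.2,
# 0.65, 0.55, 0.3 and ~0 at the default noise level). The axis-aligned part
# makes the t1t2 deficit largest at the primary-cortex (low-score) end, so
# the regional term-preterm difference anticorrelates with the axis.
DEFAULT_GROUP_SHIFT: dict[str, float] = {
    "thickness": 0.29, "t1t2": -0.73, "FA": -0.25,
    "MD": 0.53, "fICVF": -0.14, "ODI": -0.01,
}
DEFAULT_GROUP_AXIS_EFFECT: dict[str, float] = {
    "thickness": -0.04, "t1t2": 0.30, "FA": 0.05,
    "MD": -0.08, "fICVF": 0.04, "ODI": 0.01,
}


@dataclass
class SyntheticTruth:
    """Recorded ground truth of one synthetic generation.

    Only the fields relevant to the generator(s) that ran are populated;
    `seeds` accumulates one entry per generator call so that identical seeds
    regenerate byte-identical tables.
    """

    axis_region_scores: dict[str, float] = field(default_factory=dict)
    metric_loadings: dict[str, float] = field(default_factory=dict)
    participant_axis_weights: dict[str, float] = field(default_factory=dict)
    group_effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_gene_table: pd.DataFrame | None = None
    specimen_table: pd.DataFrame | None = None
    class_enrichment_plan: dict[str, float] = field(default_factory=dict)
    catalog_sets: dict[str, list[str]] = field(default_factory=dict)
    realized_class_overlap: dict[str, int] = field(default_factory=dict)
    de_composition: dict[str, int] = field(default_factory=dict)
    outlier_rows: list[dict] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def planted_genes(self) -> list[str]:
        if self.planted_gene_table is None:
            return []
        t = self.planted_gene_table
        return list(t.loc[t["direction"] != "null", "gene"])

    @property
    def gene_universe(self) -> list[str]:
        if self.planted_gene_table is None:
            return []
        return list(self.planted_gene_table["gene"])

    def to_json(self, path) -> None:
        from .io import write_json

        d = dataclasses.asdict(self)
        for key in ("planted_gene_table", "specimen_table"):
            if d[key] is not None:
                d[key] = getattr(self, key).to_dict(orient="list")
        write_json(d, path)


def _as_vector(mapping: Mapping[str, float] | None, labels: Sequence[str],
               default: Mapping[str, float]) -> np.ndarray:
    src = default if mapping is None else mapping
    return np.array([float(src[lab]) for lab in labels])


def generate_imaging_cohort(
    n_term: int = 292,
    n_preterm: int = 64,
    regions: Sequence[str] = REGIONS,
    metrics: Sequence[str] = METRICS,
    *,
    region_scores: Mapping[str, float] | None = None,
    metric_loadings: Mapping[str, float] | None = None,
    metric_means: Mapping[str, float] | None = None,
    metric_scales: Mapping[str, float] | None = None,
    axis_weight_mean: float = 1.0,
    axis_weight_sd: float = 0.25,
    group_shift: Mapping[str, float] | None = None,
    group_axis_effect: Mapping[str, float] | None = None,
    age_slope: float = 0.12,
    noise_sd: float = 0.35,
    preterm_noise_multiplier: float = 1.5,
    n_outliers: int = 0,
    outlier_scale: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a term + preterm regional-metric cohort with a planted axis.

    Each hemisphere observation is

        value = mu_m + scale_m * ( a_p * s_r * w_m
                                   + preterm * (shift_m + axis_m * s_r)
                                   + age_slope * (scan_age_w - 40)
                                   + eps ),

    with `a_p` the participant's axis weight, `s_r` the planted region score,
    `w_m` the unit-norm metric loading and `eps ~ N(0, noise_sd)` drawn
    independently per hemisphere (inflated by `preterm_noise_multiplier` off
    the axis for preterm infants). Ages are in postmenstrual/gestational
    weeks in the output table.
    """
    if n_term < 2:
        raise ValueError("n_term must be >= 2")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    if len(metrics) < 1:
        raise ValueError("need at least 1 metric")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region labels")

    rng = np.random.default_rng(seed)
    regions = list(regions)
    metrics = list(metrics)

    s = _as_vector(region_scores, regions, DEFAULT_REGION_SCORES)
    w = _as_vector(metric_loadings, metrics, DEFAULT_METRIC_LOADINGS)
    mu = _as_vector(metric_means, metrics, DEFAULT_METRIC_MEANS)
    scale = _as_vector(metric_scales, metrics, DEFAULT_METRIC_SCALES)
    shift = _as_vector(group_shift, metrics, DEFAULT_GROUP_SHIFT)
    axis_eff = _as_vector(group_axis_effect, metrics, DEFAULT_GROUP_AXIS_EFFECT)

    n_total = n_term + n_preterm
    ids = [f"sub-{i:04d}" for i in range(n_total)]
    if len(set(ids)) != len(ids):  # defensive; ids are generated
        raise ValueError("duplicate participant identifiers")
    is_preterm = np.array([False] * n_term + [True] * n_preterm)

    birth = np.where(
        is_preterm,
        np.clip(rng.normal(32.0, 3.9, n_total), 24.0, 36.9),
        np.clip(rng.normal(40.0, 1.2, n_total), 37.0, 42.0),
    )
    scan = np.where(
        is_preterm,
        np.clip(rng.normal(40.5, 1.3, n_total), 38.0, 44.5),
        np.clip(birth + rng.uniform(0.3, 2.5, n_total), 37.3, 44.7),
    )
    sex = rng.integers(0, 2, n_total)  # 0 = female, 1 = male
    a = rng.normal(axis_weight_mean, axis_weight_sd, n_total)

    n_r, n_m = len(regions), len(metrics)
    # broadcast to (participant, region, metric, hemisphere)
    signal = a[:, None, None] * s[None, :, None] * w[None, None, :]
    signal = signal + is_preterm[:, None, None] * (
        shift[None, None, :] + axis_eff[None, None, :] * s[None, :, None]
    )
    signal = signal + age_slope * (scan - 40.0)[:, None, None]
    signal = np.repeat(signal[..., None], 2, axis=3)
    eps_sd = np.where(is_preterm, noise_sd * preterm_noise_multiplier, noise_sd)
    signal = signal + rng.normal(0.0, 1.0, signal.shape) * eps_sd[:, None, None, None]
    values = mu[None, None, :, None] + scale[None, None, :, None] * signal

    idx = pd.MultiIndex.from_product(
        [ids, regions, metrics, ["L", "R"]],
        names=["participant_id", "region", "metric", "hemisphere"],
    )
    table = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
    meta = pd.DataFrame({
        "participant_id": ids,
        "group": np.where(is_preterm, "preterm", "term"),
        "age_at_scan": scan,
        "age_at_birth": birth,
        "sex": np.where(sex == 1, "M", "F"),
    })
    table = table.merge(meta, on="participant_id")
    table = table[[
        "participant_id", "group", "age_at_scan", "age_at_birth", "sex",
        "region", "hemisphere", "metric", "value",
    ]]

    truth = SyntheticTruth(
        axis_region_scores=dict(zip(regions, s)),
        metric_loadings=dict(zip(metrics, w)),
        participant_axis_weights=dict(zip(ids, a)),
        group_effect_sizes={
            "shift": dict(zip(metrics, shift)),
            "axis_aligned": dict(zip(metrics, axis_eff)),
        },
        seeds={"imaging": int(seed)},
        params={
            "n_term": n_term, "n_preterm": n_preterm, "noise_sd": noise_sd,
            "age_slope": age_slope,
            "preterm_noise_multiplier": preterm_noise_multiplier,
        },
    )

    if n_outliers > 0:
        rows = rng.choice(len(table), size=n_outliers, replace=False)
        for r in rows:
            m = table.loc[r, "metric"]
            table.loc[r, "value"] += outlier_scale * scale[metrics.index(m)]
            truth.outlier_rows.append({
                "participant_id": table.loc[r, "participant_id"],
                "region": table.loc[r, "region"],
                "metric": m,
                "hemisphere": table.loc[r, "hemisphere"],
            })
    return table, truth


def delta_for_tau(target_tau: float, noise_sd: float,
                  region_scores: Sequence[float]) -> float:
    """Spatial effect size (log2 units per unit score) giving a population
    Kendall tau of `target_tau` between residual expression and score under
    Gaussian noise (Greiner's relation tau = (2/pi) asin(rho))."""
    rho = np.sin(np.pi * target_tau / 2.0)
    sigma_s = float(np.std(region_scores))
    if rho >= 1.0 or sigma_s == 0:
        raise ValueError("unattainable target tau")
    return float(rho * noise_sd / (sigma_s * np.sqrt(1.0 - rho * rho)))


def generate_expression_atlas(
    n_specimens: int = 16,
    age_range: tuple[float, float] = (84.0, 259.0),
    regions: Sequence[str] = REGIONS,
    n_genes: int = 2000,
    n_planted_pos: int = 60,
    n_planted_neg: int = 60,
    missing_region_rate: float = 0.11,
    *,
    region_scores: Mapping[str, float] | None = None,
    target_tau: float = 0.3,
    delta: float | None = None,
    specimen_sd: float = 0.3,
    beta_sex_sd: float = 0.2,
    beta_rin_sd: float = 0.1,
    noise_sd: float = 0.5,
    base_mean: float = 4.0,
    base_sd: float = 1.5,
    traj_coef_sds: tuple[float, float, float] = (1.0, 0.5, 0.25),
    rin_range: tuple[float, float] = (8.0, 10.0),
    min_regions: int = 3,
    allowed_age_span: tuple[float, float] = (50.0, 400.0),
    maturity_gradient: float = 0.0,
    region_age_offsets: Mapping[str, float] | None = None,
    spatial_window: tuple[float, float] | None = None,
    spatial_ramp_days: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a bulk prenatal expression atlas with planted spatial genes.

    Per gene g and sample (specimen s, region r), the log2-scale signal is

        f_g(age_s) + beta_sex * sex_s + beta_rin * (rin_s - rin_mid)
            + b_s + delta_g * score_r + eps,

    with f_g a cubic polynomial in scaled age and RPKM = 2**signal (always
    strictly positive). `delta_g` is nonzero only for the planted genes; its
    default magnitude is derived from `target_tau` via `delta_for_tau`. Each
    specimen loses regions independently at `missing_region_rate`, never
    dropping below `min_regions`.

    Regional maturation offsets can be planted by evaluating the trajectories
    at a shifted effective age: `region_age_offsets` adds a fixed per-region
    offset (days), and `maturity_gradient` adds
    -score_r * (age - lo) / (hi - lo) * gradient days, i.e. an anticorrelation
    of regional maturity with the axis score that grows over gestation.

    `spatial_window` restricts the planted spatial gradient to an age
    interval: delta is scaled by linear ramps of `spatial_ramp_days` into and
    out of [start, end] (1 inside, 0 well outside), emulating genes whose
    regional patterning is confined to part of gestation.
    """
    if n_planted_pos + n_planted_neg > n_genes:
        raise ValueError("planted counts exceed n_genes")
    if len(regions) == 0:
        raise ValueError("empty region list")
    lo, hi = age_range
    if not (allowed_age_span[0] <= lo < hi <= allowed_age_span[1]):
        raise ValueError(f"age range {age_range} outside allowed span {allowed_age_span}")

    rng = np.random.default_rng(seed)
    regions = list(regions)
    s_vec = _as_vector(region_scores, regions, DEFAULT_REGION_SCORES)
    score_by_region = dict(zip(regions, s_vec))

    if delta is None:
        delta = delta_for_tau(target_tau, noise_sd, s_vec) if target_tau else 0.0

    spec_ids = [f"spec-{i:02d}" for i in range(n_specimens)]
    # first/last specimens pinned at the range endpoints so fitted spans cover
    # the full window (as a designed age-sampling scheme would)
    if n_specimens >= 2:
        ages = np.sort(np.concatenate([[lo], rng.uniform(lo, hi, n_specimens - 2), [hi]]))
    else:
        ages = rng.uniform(lo, hi, n_specimens)
    sexes = rng.integers(0, 2, n_specimens)
    rins = rng.uniform(rin_range[0], rin_range[1], n_specimens)
    rin_mid = float(np.mean(rin_range))
    b_s = rng.normal(0.0, specimen_sd, n_specimens) if specimen_sd > 0 else np.zeros(n_specimens)

    # region sampling per specimen
    sampled: list[list[int]] = []
    for _ in range(n_specimens):
        keep = np.where(rng.uniform(size=len(regions)) >= missing_region_rate)[0]
        if len(keep) < min_regions:
            keep = rng.choice(len(regions), size=min_regions, replace=False)
            keep.sort()
        sampled.append(list(keep))

    genes = [f"G{i:05d}" for i in range(n_genes)]
    direction = np.array(["null"] * n_genes, dtype=object)
    direction[:n_planted_pos] = "+"
    direction[n_planted_pos:n_planted_pos + n_planted_neg] = "-"
    # shuffle so planted genes are not the lexicographic head of the universe
    order = rng.permutation(n_genes)
    direction = direction[order]
    deltas = np.where(direction == "+", delta, np.where(direction == "-", -delta, 0.0))

    c0 = rng.normal(base_mean, base_sd, n_genes)
    c1 = rng.normal(0.0, traj_coef_sds[0], n_genes)
    c2 = rng.normal(0.0, traj_coef_sds[1], n_genes)
    c3 = rng.normal(0.0, traj_coef_sds[2], n_genes)
    beta_sex = rng.normal(0.0, beta_sex_sd, n_genes) if beta_sex_sd > 0 else np.zeros(n_genes)
    beta_rin = rng.normal(0.0, beta_rin_sd, n_genes) if beta_rin_sd > 0 else np.zeros(n_genes)

    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0

    # flatten sample grid
    spec_idx = np.concatenate([[i] * len(sampled[i]) for i in range(n_specimens)]).astype(int)
    reg_idx = np.concatenate([sampled[i] for i in range(n_specimens)]).astype(int)
    n_samples = len(spec_idx)

    eff_age = ages[spec_idx].copy()
    if maturity_gradient != 0.0:
        eff_age = eff_age + (-s_vec[reg_idx]) * maturity_gradient \
            * (ages[spec_idx] - lo) / (hi - lo)
    if region_age_offsets:
        off = np.array([float(region_age_offsets.get(regions[j], 0.0))
                        for j in reg_idx])
        eff_age = eff_age + off
    t = (eff_age - mid) / half
    # (samples, genes)
    f = (c0[None, :] + c1[None, :] * t[:, None]
         + c2[None, :] * (t ** 2)[:, None] + c3[None, :] * (t ** 3)[:, None])
    if spatial_window is not None:
        ws, we = spatial_window
        ramp = max(spatial_ramp_days, 1e-9)
        age_s = ages[spec_idx]
        wt = (np.clip((age_s - ws) / ramp + 1.0, 0.0, 1.0)
              * np.clip((we - age_s) / ramp + 1.0, 0.0, 1.0))
    else:
        wt = np.ones(n_samples)
    signal = (f
              + beta_sex[None, :] * sexes[spec_idx, None]
              + beta_rin[None, :] * (rins[spec_idx] - rin_mid)[:, None]
              + b_s[spec_idx, None]
              + deltas[None, :] * (s_vec[reg_idx] * wt)[:, None])
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    rpkm = np.exp2(signal)

    table = pd.DataFrame({
        "specimen_id": np.repeat([spec_ids[i] for i in spec_idx], n_genes),
        "region": np.repeat([regions[i] for i in reg_idx], n_genes),
        "age": np.repeat(ages[spec_idx], n_genes),
        "sex": np.repeat(np.where(sexes[spec_idx] == 1, "M", "F"), n_genes),
        "rin": np.repeat(rins[spec_idx], n_genes),
        "gene": np.tile(genes, n_samples),
        "rpkm": rpkm.ravel(),
    })

    planted_table = pd.DataFrame({
        "gene": genes, "direction": direction, "delta": deltas,
        "c0": c0, "c1": c1, "c2": c2, "c3": c3,
        "beta_sex": beta_sex, "beta_rin": beta_rin,
        "specimen_sd": specimen_sd, "noise_sd": noise_sd,
    })
    specimen_table = pd.DataFrame({
        "specimen_id": spec_ids, "age": ages,
        "sex": np.where(sexes == 1, "M", "F"), "rin": rins,
        "intercept": b_s,
        "n_regions": [len(k) for k in sampled],
        "regions": [",".join(regions[j] for j in k) for k in sampled],
    })
    truth = SyntheticTruth(
        axis_region_scores=score_by_region,
        planted_gene_table=planted_table,
        specimen_table=specimen_table,
        seeds={"expression": int(seed)},
        params={
            "n_specimens": n_specimens, "age_range": list(age_range),
            "delta": float(delta), "target_tau": target_tau,
            "noise_sd": noise_sd, "specimen_sd": specimen_sd,
            "missing_region_rate": missing_region_rate,
            "maturity_gradient": maturity_gradient,
            "region_age_offsets": dict(region_age_offsets or {}),
            "spatial_window": list(spatial_window) if spatial_window else None,
        },
    )
    return table, truth


def generate_geneset_catalog(
    truth: SyntheticTruth,
    class_names: Sequence[str] | None = None,
    markers_per_class: int = 40,
    overlap_rate: float = 0.1,
    enrichment_plan: Mapping[str, float] | None = None,
    seed: int = 0,
):
    """Build a marker-gene catalog over the generated universe.

    `enrichment_plan` maps class name -> fraction of that class's markers
    drawn from the planted (axis-associated) genes; unmapped classes get 0.
    The realized overlap of each class with the planted set is recorded in
    `truth.realized_class_overlap`. Returns a
    :class:`~natalaxis.enrichment.GeneSetCatalog`.
    """
    from .enrichment import GeneSetCatalog

    universe = truth.gene_universe
    if not universe:
        raise ValueError("truth has no generated gene universe")
    if markers_per_class > len(universe):
        raise ValueError("markers_per_class exceeds universe size")
    class_names = list(class_names or DEFAULT_CELL_CLASSES)
    enrichment_plan = dict(enrichment_plan or {})

    rng = np.random.default_rng(seed)
    planted = truth.planted_genes
    nonplanted = [g for g in universe if g not in set(planted)]

    # Base sets are disjoint across classes; overlap_rate injects sharing
    # below. Classes without a planted fraction sample uniformly from the
    # whole (unused) universe, so their overlap with the planted set follows
    # the hypergeometric null.
    used: set[str] = set()
    sets: dict[str, list[str]] = {}
    for cls in class_names:
        frac = float(enrichment_plan.get(cls, 0.0))
        chosen: list[str] = []
        if frac > 0:
            planted_pool = [g for g in planted if g not in used]
            n_from_planted = min(int(round(frac * markers_per_class)),
                                 len(planted_pool))
            if n_from_planted:
                chosen += list(rng.choice(planted_pool, size=n_from_planted,
                                          replace=False))
            pool = [g for g in nonplanted if g not in used]
        else:
            pool = [g for g in universe if g not in used]
        n_rest = markers_per_class - len(chosen)
        if n_rest > len(pool):
            raise ValueError("not enough unused genes for disjoint class sets")
        chosen += list(rng.choice(pool, size=n_rest, replace=False))
        used.update(chosen)
        sets[cls] = sorted(map(str, chosen))

    if overlap_rate > 0 and len(class_names) > 1:
        for cls in class_names:
            n_shared = int(np.floor(overlap_rate * markers_per_class))
            if n_shared == 0:
                continue
            others = [g for c2, gl in sets.items() if c2 != cls for g in gl
                      if g not in set(sets[cls])]
            if not others:
                continue
            take = list(rng.choice(sorted(set(others)),
                                   size=min(n_shared, len(set(others))), replace=False))
            # replace non-planted tail markers to preserve planted overlap
            keep = [g for g in sets[cls] if g in set(planted)]
            rest = [g for g in sets[cls] if g not in set(planted)]
            rest = rest[: markers_per_class - len(keep) - len(take)]
            sets[cls] = sorted(keep + rest + take)

    class_meta = {
        cls: dict(DEFAULT_CELL_CLASSES.get(cls, {"lineage": "other", "timing": "mature"}),
                  source="synthetic")
        for cls in class_names
    }
    catalog = GeneSetCatalog(sets=sets, class_meta=class_meta, universe=list(universe))

    planted_set = set(planted)
    truth.class_enrichment_plan = {c: float(enrichment_plan.get(c, 0.0)) for c in class_names}
    truth.realized_class_overlap = {c: len(planted_set & set(g)) for c, g in sets.items()}
    truth.catalog_sets = {c: list(g) for c, g in sets.items()}
    truth.seeds["catalog"] = int(seed)
    return catalog, truth


def generate_de_genelist(
    truth: SyntheticTruth,
    n_de: int = 217,
    fraction_from_class: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[str], SyntheticTruth]:
    """Draw a differential-expression gene list with a recorded class mix."""
    universe = truth.gene_universe
    if n_de > len(universe):
        raise ValueError("n_de exceeds universe size")
    fractions = dict(fraction_from_class or {})
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("requested class fractions sum to more than 1")

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    composition: dict[str, int] = {}
    for cls, frac in fractions.items():
        pool = [g for g in truth.catalog_sets.get(cls, []) if g not in set(chosen)]
        k = min(int(round(frac * n_de)), len(pool))
        if k:
            chosen += list(rng.choice(pool, size=k, replace=False))
        composition[cls] = k
    remainder_pool = [g for g in universe if g not in set(chosen)]
    n_rest = n_de - len(chosen)
    if n_rest > 0:
        chosen += list(rng.choice(remainder_pool, size=n_rest, replace=False))
    composition["background"] = n_rest

    truth.de_composition = composition
    truth.seeds["de_list"] = int(seed)
    return sorted(chosen), truth
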