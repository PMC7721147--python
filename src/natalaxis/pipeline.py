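"""End-to-end orchestration with a single config and per-stage seeds.

`run_all` executes: simulate -> axis -> trajectories -> associate -> enrich
-> maturity -> groupdiff -> windows, writing plain TSV/JSON outputs and a
machine-readable run report (config echo, seeds, input hashes, per-stage
headline statistics). Every stochastic stage consumes an explicit seed from
the config; there is no hidden global RNG state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    enrichment as enr,
    groupdiff as gd,
    imaging,
    maturity as mat,
    spatial,
    syndata,
    trajectories as traj,
    windowed as win,
)
from .io import write_gene_list, write_json, write_table
from .vocab import METRICS, REGIONS

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable pipeline constants, serialisable to/from YAML."""

    out_dir: str = "results"
    metrics_path: str | None = None
    expression_path: str | None = None
    catalog_path: str | None = None
    de_list_path: str | None = None
    simulate: bool = True

    # analysis constants
    mad_threshold: float = 3.5
    fdr_alpha: float = 0.05
    winsor_percentiles: tuple[float, float] = (5.0, 95.0)
    spline_knots: int = 4
    grid_points: int = 50
    svr_C: float = 10.0
    svr_epsilon: float = 0.1
    n_boot: int = 1000
    n_perm_maturity: int = 5000
    n_perm_foldchange: int = 10000
    windows: tuple[float, float, int] = (160.0, 260.0, 10)
    n_components: int = 2

    # simulation sizes (demo-scale defaults; study-scale cohort sizes are the
    # generator's own defaults)
    sim_n_term: int = 292
    sim_n_preterm: int = 64
    sim_n_specimens: int = 21
    sim_age_range: tuple[float, float] = (56.0, 380.0)
    sim_n_genes: int = 400
    sim_n_planted_pos: int = 30
    sim_n_planted_neg: int = 30
    sim_markers_per_class: int = 30
    sim_maturity_gradient: float = 20.0
    sim_enrichment_plan: dict = field(
        default_factory=lambda: {"intermediate_progenitor": 0.5, "microglia": 0.3})
    sim_n_de: int = 100
    sim_de_fractions: dict = field(default_factory=lambda: {"microglia": 0.4})

    fit_linear_models: bool = True
    max_region_fit_genes: int = 200

    seeds: dict = field(default_factory=lambda: {
        "imaging": 101, "expression": 202, "catalog": 303, "de_list": 404,
        "foldchange": 505, "bootstrap": 606, "maturity_perm": 707,
        "embedding": 808,
    })

    def __post_init__(self):
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        for name in ("spline_knots", "grid_points", "n_boot",
                     "n_perm_maturity", "n_perm_foldchange", "n_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["winsor_percentiles"] = list(self.winsor_percentiles)
        d["windows"] = list(self.windows)
        d["sim_age_range"] = list(self.sim_age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("winsor_percentiles", "windows", "sim_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.md5(df.to_csv(index=False).encode()).hexdigest()


def validate_inputs(metric_table: pd.DataFrame | None = None,
                    expression_table: pd.DataFrame | None = None) -> dict:
    """Vocabulary, uniqueness-key, range and age-unit checks.

    Returns {"errors": [...], "warnings": [...]}; callers decide whether to
    abort on errors.
    """
    errors, warnings_ = [], []
    if metric_table is not None:
        bad_regions = set(metric_table["region"]) - set(REGIONS)
        if bad_regions:
            errors.append(f"unknown region labels {sorted(bad_regions)}; "
                          f"allowed: {list(REGIONS)}")
        bad_metrics = set(metric_table["metric"]) - set(METRICS)
        if bad_metrics:
            errors.append(f"unknown metric labels {sorted(bad_metrics)}; "
                          f"allowed: {list(METRICS)}")
        keys = ["participant_id", "region", "metric"]
        if "hemisphere" in metric_table.columns:
            keys.append("hemisphere")
        if metric_table.duplicated(subset=keys).any():
            errors.append("duplicated (participant, region, hemisphere, metric) rows")
        scan = metric_table.get("age_at_scan")
        if scan is not None and scan.median() > 100:
            warnings_.append("age_at_scan looks like days; weeks expected "
                             "(divide by 7)")
    if expression_table is not None:
        if (expression_table["rpkm"] < 0).any():
            errors.append("negative RPKM values")
        if expression_table.duplicated(subset=["specimen_id", "region", "gene"]).any():
            errors.append("duplicated (specimen, region, gene) rows")
        age = expression_table["age"]
        if age.median() < 50:
            warnings_.append("expression ages look like weeks; postconceptional "
                             "days expected (multiply by 7)")
        bad_regions = set(expression_table["region"]) - set(REGIONS)
        if bad_regions:
            errors.append(f"unknown region labels {sorted(bad_regions)}; "
                          f"allowed: {list(REGIONS)}")
    return {"errors": errors, "warnings": warnings_}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seeds": dict(cfg.seeds),
                    "config": dataclasses.asdict(cfg)}
    t_start = time.time()

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = {"status": "running"}
        return time.time()

    def done(name, t0, **stats):
        report["stages"][name].update(status="succeeded",
                                      seconds=round(time.time() - t0, 2), **stats)

    try:
        # ------------------------------------------------------------ simulate
        t0 = stage("simulate")
        if cfg.simulate:
            metric_table, img_truth = syndata.generate_imaging_cohort(
                n_term=cfg.sim_n_term, n_preterm=cfg.sim_n_preterm,
                seed=cfg.seeds["imaging"])
            expr_table, expr_truth = syndata.generate_expression_atlas(
                n_specimens=cfg.sim_n_specimens, age_range=cfg.sim_age_range,
                n_genes=cfg.sim_n_genes, n_planted_pos=cfg.sim_n_planted_pos,
                n_planted_neg=cfg.sim_n_planted_neg,
                maturity_gradient=cfg.sim_maturity_gradient,
                seed=cfg.seeds["expression"])
            catalog, expr_truth = syndata.generate_geneset_catalog(
                expr_truth, markers_per_class=cfg.sim_markers_per_class,
                enrichment_plan=cfg.sim_enrichment_plan,
                seed=cfg.seeds["catalog"])
            de_list, expr_truth = syndata.generate_de_genelist(
                expr_truth, n_de=cfg.sim_n_de,
                fraction_from_class=cfg.sim_de_fractions,
                seed=cfg.seeds["de_list"])
            write_table(metric_table, out / "metric_table.tsv")
            write_table(expr_table, out / "expression_table.tsv")
            catalog.to_gmt(out / "catalog.gmt")
            write_gene_list(de_list, out / "de_genes.txt")
            expr_truth.to_json(out / "truth_expression.json")
            img_truth.to_json(out / "truth_imaging.json")
        else:
            from .io import read_gene_list, read_table
            for attr, label in (("metrics_path", "metric table"),
                                ("expression_path", "expression table")):
                if getattr(cfg, attr) is None or not Path(getattr(cfg, attr)).exists():
                    raise FileNotFoundError(
                        f"{label} not found at {getattr(cfg, attr)!r} and "
                        "simulate flag is off")
            metric_table = read_table(cfg.metrics_path)
            expr_table = read_table(cfg.expression_path)
            catalog = enr.GeneSetCatalog.from_gmt(
                cfg.catalog_path, universe=sorted(expr_table["gene"].unique()))
            de_list = read_gene_list(cfg.de_list_path) if cfg.de_list_path else []
            img_truth = expr_truth = None
        checks = validate_inputs(metric_table, expr_table)
        if checks["errors"]:
            raise ValueError("input validation failed: " + "; ".join(checks["errors"]))
        done("simulate", t0,
             metric_rows=len(metric_table), expression_rows=len(expr_table),
             metric_hash=_hash_frame(metric_table),
             expression_hash=_hash_frame(expr_table),
             warnings=checks["warnings"])

        # ---------------------------------------------------------------- axis
        t0 = stage("axis")
        term = metric_table[metric_table["group"] == "term"]
        axis, zparams = imaging.compute_axis(
            term, n_components=cfg.n_components, mad_threshold=cfg.mad_threshold)
        scores_table = imaging.project_cohort(metric_table, axis)
        write_table(axis.scores_frame().reset_index(names="region"),
                    out / "axis_region_scores.tsv")
        write_table(scores_table, out / "participant_axis_scores.tsv")
        done("axis", t0,
             pc1_variance_pct=float(100 * axis.variance_fraction[0]),
             pc2_variance_pct=float(100 * axis.variance_fraction[1])
             if cfg.n_components > 1 else None)

        # -------------------------------------------------------- trajectories
        t0 = stage("trajectories")
        expr = traj.preprocess_expression(
            expr_table, *cfg.winsor_percentiles, min_obs=10)
        fits = traj.fit_all_genes(expr, n_knots=cfg.spline_knots,
                                  fit_linear=cfg.fit_linear_models)
        residuals = traj.age_corrected_expression(fits, expr)
        write_table(residuals.reset_index(), out / "age_corrected_residuals.tsv")
        if cfg.fit_linear_models:
            deltas = {g: traj.compare_models(f) for g, f in fits.items()}
            delta_aic = float(np.median([d[0] for d in deltas.values()]))
        else:
            delta_aic = None
        done("trajectories", t0, n_genes_fit=len(fits),
             median_delta_aic=delta_aic)

        # ----------------------------------------------------------- associate
        t0 = stage("associate")
        assoc = spatial.correlate_genes_with_axis(
            residuals, axis.pc1_scores, alpha=cfg.fdr_alpha)
        sets = spatial.significant_sets(assoc)
        write_table(assoc, out / "gene_axis_association.tsv")
        for name, genes in sets.items():
            write_gene_list(genes, out / f"genes_{name.replace('+', 'pos').replace('-', 'neg')}.txt")
        top = axis.pc1_scores.nlargest(3).index.tolist()
        bottom = axis.pc1_scores.nsmallest(2).index.tolist()
        mean_expr = expr.pivot_table(index="gene", columns="region",
                                     values="rpkm", aggfunc="mean")
        if sets["PC+"]:
            fc, fc_p = spatial.fold_change_permutation_test(
                mean_expr, sets["PC+"], top, bottom,
                n_perm=cfg.n_perm_foldchange, seed=cfg.seeds["foldchange"])
        else:
            fc, fc_p = np.nan, np.nan
        done("associate", t0, n_significant=int((assoc["set_label"] != "null").sum()),
             n_pc_pos=len(sets["PC+"]), n_pc_neg=len(sets["PC-"]),
             fold_change=fc, fold_change_p=fc_p)

        # -------------------------------------------------------------- enrich
        t0 = stage("enrich")
        enrich_tables = enr.run_class_enrichment(
            {k: v for k, v in sets.items() if v}, catalog, background="all")
        write_table(enrich_tables, out / "class_enrichment.tsv")
        top_row = (enrich_tables.sort_values("p").iloc[0]
                   if len(enrich_tables) else None)
        done("enrich", t0,
             top_set=None if top_row is None else str(top_row["set_name"]),
             top_ratio=None if top_row is None else float(top_row["enrichment_ratio"]))

        # ------------------------------------------------------------ maturity
        t0 = stage("maturity")
        pc_genes = sets["PC+"] + sets["PC-"]
        expr_pc = expr[expr["gene"].isin(pc_genes)] if pc_genes else expr
        fits_pc = {g: fits[g] for g in (pc_genes or fits)} if pc_genes else fits
        regional, spec_means, ages = mat.age_retained_expression(fits_pc, expr_pc)
        preds = mat.loo_svr_age_prediction(spec_means, ages, regional,
                                           C=cfg.svr_C, epsilon=cfg.svr_epsilon)
        merged = preds.merge(ages.rename("age"), left_on="specimen_id",
                             right_index=True)
        pred_r = float(np.corrcoef(merged["predicted_age"], merged["age"])[0, 1])
        boot = mat.bootstrap_maturity(spec_means, ages, regional,
                                      n_boot=cfg.n_boot, C=cfg.svr_C,
                                      epsilon=cfg.svr_epsilon,
                                      seed=cfg.seeds["bootstrap"])
        write_table(boot, out / "maturity_predictions.tsv")
        axis_test = mat.maturity_axis_test(
            spec_means, ages, regional, axis.pc1_scores,
            n_perm=cfg.n_perm_maturity, C=cfg.svr_C, epsilon=cfg.svr_epsilon,
            seed=cfg.seeds["maturity_perm"])
        write_json({"slope": axis_test.slope, "r_squared": axis_test.r_squared,
                    "permutation_p": axis_test.permutation_p,
                    "n_perm": axis_test.n_perm},
                   out / "maturity_axis_test.json")
        done("maturity", t0, prediction_r=pred_r,
             r_squared=axis_test.r_squared,
             permutation_p=axis_test.permutation_p)

        # ------------------------------------------------------------ groupdiff
        t0 = stage("groupdiff")
        mixed = gd.fit_all_metric_models(metric_table, axis)
        coef_rows = []
        for m, res in mixed.items():
            c = res.coefficients.copy()
            c.insert(0, "metric", m)
            c["cohens_d"] = res.cohens_d
            coef_rows.append(c)
        write_table(pd.concat(coef_rows, ignore_index=True),
                    out / "group_mixed_models.tsv")
        ancova = gd.compare_variance_explained(scores_table)
        write_table(ancova.reset_index(names="term"), out / "variance_ancova.tsv")
        profile = gd.regional_difference_vs_axis(metric_table, axis)
        write_table(profile.summary, out / "group_difference_vs_axis.tsv")
        t1t2_row = profile.summary.set_index("metric").loc["t1t2"] \
            if "t1t2" in profile.summary["metric"].values else None
        done("groupdiff", t0,
             ancova_group_F=float(ancova.loc["group", "F"]),
             ancova_group_p=float(ancova.loc["group", "PR(>F)"]),
             t1t2_cohens_d=mixed["t1t2"].cohens_d if "t1t2" in mixed else None,
             t1t2_diff_vs_axis_r=None if t1t2_row is None
             else float(t1t2_row["pearson_r"]))

        # -------------------------------------------------------------- windows
        t0 = stage("windows")
        w_lo, w_hi, n_win = cfg.windows
        windows = win.make_age_windows(w_lo, w_hi, int(n_win))
        region_genes = sorted(set(catalog.all_marker_genes()) & set(fits))
        if len(region_genes) > cfg.max_region_fit_genes:
            region_genes = region_genes[:cfg.max_region_fit_genes]
        region_fits = {}
        for g in region_genes:
            sub = expr[expr["gene"] == g]
            fit = fits[g]
            fit.region_fit = traj.fit_region_trajectories(sub, n_knots=cfg.spline_knots)
            region_fits[g] = fit
        n_points = max(cfg.grid_points, 10 * int(n_win))
        grids = traj.trajectory_grids(region_fits, (w_lo, w_hi), n_points)
        wmeans = win.window_mean_expression(grids, windows)
        diff = (profile.table[profile.table["metric"] == "t1t2"]
                .set_index("region")["mean_difference"])
        wassoc = win.window_gene_association(wmeans, diff, alpha=cfg.fdr_alpha)
        wsets = win.significant_window_sets(wassoc)
        background = sorted(set(grids["gene"].unique()))
        wenrich = win.window_cell_enrichment(wsets, catalog, background)
        write_table(wassoc, out / "window_associations.tsv")
        write_table(wenrich, out / "window_class_enrichment.tsv")
        if de_list:
            overlap = win.cross_study_overlap(de_list, wsets, catalog,
                                              background)
            write_table(overlap, out / "cross_study_overlap.tsv")
        done("windows", t0,
             n_window_genes=len(region_genes),
             n_significant_by_window={int(k): len(v) for k, v in wsets.items()})

    except Exception as exc:
        failed = [k for k, v in report["stages"].items()
                  if v.get("status") == "running"]
        name = failed[0] if failed else "unknown"
        report["stages"][name] = {"status": "failed", "error": str(exc)}
        report["elapsed_seconds"] = round(time.time() - t_start, 2)
        write_json(report, out / "run_report.json")
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    report["elapsed_seconds"] = round(time.time() - t_start, 2)
    write_json(report, out / "run_report.json")
    return report
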