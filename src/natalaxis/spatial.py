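"""Spatial association between age-corrected expression and the imaging axis.

For each gene, the residuals of the nonlinear age model (one value per
specimen x region sample) are rank-correlated (Kendall's tau-b) with the
PC1 score of the sample's region. P-values are corrected across genes with
the Benjamini–Hochberg FDR and significant genes are split into PC+ (tau > 0)
and PC- (tau < 0) sets. A permutation fold-change test validates planted or
observed set-level expression differences between region groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-adjusted Kendall tau-b with two-sided p.

    Exact p for small samples without ties, normal approximation with tie
    correction otherwise. A fully tied input is degenerate: tau reported as
    0 with p = 1 (logged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    if len(x) < 3:
        raise ValueError("need length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.info("degenerate (all-tied) vector in kendall_tau; tau=0, p=1")
        return 0.0, 1.0
    res = stats.kendalltau(x, y, variant="b", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_genes_with_axis(
    residuals: pd.DataFrame,
    axis_scores: pd.Series,
    alpha: float = 0.05,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Gene-by-gene Kendall correlation with the regional PC1 score.

    `residuals` is the sample x gene matrix indexed by (specimen_id, region);
    `axis_scores` maps region -> PC1 score. In the default per-sample mode
    every (specimen, region) sample enters the correlation; `region_mean`
    aggregates residuals to region means first. Returns a table with columns
    gene, tau, p, q, set_label (PC+, PC-, null).
    """
    if mode not in ("per_sample", "region_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    regions = residuals.index.get_level_values("region")
    missing = set(regions) - set(axis_scores.index)
    if missing:
        raise ValueError(f"regions without axis score: {sorted(missing)}")

    if mode == "region_mean":
        agg = residuals.groupby(level="region").mean()
        scores = axis_scores.reindex(agg.index).to_numpy()
        data = agg
    else:
        scores = axis_scores.reindex(regions).to_numpy()
        data = residuals

    rows = []
    for gene in data.columns:
        vals = data[gene].to_numpy(float)
        ok = ~np.isnan(vals)
        if ok.sum() < 3:
            log.info("gene %s skipped: fewer than 3 valid samples", gene)
            continue
        tau, p = kendall_tau(vals[ok], scores[ok])
        rows.append({"gene": gene, "tau": tau, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no genes with enough valid samples")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["set_label"] = "null"
    out.loc[(out["q"] < alpha) & (out["tau"] > 0), "set_label"] = "PC+"
    out.loc[(out["q"] < alpha) & (out["tau"] < 0), "set_label"] = "PC-"
    return out


def significant_sets(assoc: pd.DataFrame) -> dict[str, list[str]]:
    """PC+ / PC- gene lists from an association table."""
    return {
        "PC+": sorted(assoc.loc[assoc["set_label"] == "PC+", "gene"]),
        "PC-": sorted(assoc.loc[assoc["set_label"] == "PC-", "gene"]),
    }


def fold_change_permutation_test(
    expression: pd.DataFrame,
    gene_set: list[str],
    regions_a: list[str],
    regions_b: list[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Set-level fold change between two region groups with a gene-resampling null.

    `expression` is a gene x region matrix on a linear (positive) scale. The
    statistic is the mean over the gene set of
    (mean expression in regions A) / (mean expression in regions B); the null
    draws `n_perm` random gene sets of equal size from the background rows.
    Returns (mean fold change, add-one permutation p for enrichment of A).
    """
    if set(regions_a) & set(regions_b):
        raise ValueError("region groups must be disjoint")
    gene_set = [g for g in dict.fromkeys(gene_set)]
    if not gene_set:
        raise ValueError("empty gene set")
    if len(gene_set) > len(expression):
        raise ValueError("gene set larger than background")
    missing = set(gene_set) - set(expression.index)
    if missing:
        raise ValueError(f"genes missing from expression matrix: {sorted(missing)[:5]}")

    ratio = (expression[list(regions_a)].mean(axis=1)
             / expression[list(regions_b)].mean(axis=1))
    observed = float(ratio.loc[gene_set].mean())

    rng = np.random.default_rng(seed)
    all_ratios = ratio.to_numpy(float)
    k = len(gene_set)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(all_ratios), size=k, replace=False)
        null[i] = all_ratios[idx].mean()
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return observed, p
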