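"""Time-resolved association of gene expression with group differences.

The late-gestation period (~160-260 postconceptional days) is split into 10
equal-width age windows. Modelled region-specific expression trajectories are
averaged within each window, and per window each gene's regional expression
profile is rank-correlated (Kendall's tau, exact p for the ~11 region pairs)
with the regional term-preterm difference in one imaging metric. Per-window
significant gene sets (BH-FDR within window) then feed cell-class enrichment
and cross-study overlap with an external differential-expression list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import GeneSetCatalog, hypergeom_ora
from .spatial import bh_fdr, kendall_tau

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeWindow:
    index: int                  # 1-based
    start: float                # postconceptional days, inclusive
    end: float                  # exclusive except for the last window


def make_age_windows(start: float = 160.0, end: float = 260.0,
                     n: int = 10) -> list[AgeWindow]:
    """`n` contiguous equal-width windows over [start, end]."""
    if end <= start:
        raise ValueError("end must exceed start")
    if n < 1:
        raise ValueError("need n >= 1")
    edges = np.linspace(start, end, n + 1)
    return [AgeWindow(i + 1, float(edges[i]), float(edges[i + 1]))
            for i in range(n)]


def window_mean_expression(
    grids: pd.DataFrame, windows: list[AgeWindow]
) -> dict[int, pd.DataFrame]:
    """Mean of dense-grid predictions per window: window -> gene x region.

    `grids` is the long trajectory table (gene, region, age, predicted_log2).
    A window containing no grid points is an error (raise the grid density).
    """
    ages = grids["age"].to_numpy(float)
    out: dict[int, pd.DataFrame] = {}
    for w in windows:
        last = w.index == len(windows)
        mask = (ages >= w.start) & ((ages <= w.end) if last else (ages < w.end))
        sub = grids[mask]
        if sub.empty:
            raise ValueError(f"window {w.index} [{w.start}, {w.end}) contains "
                             "no grid points; increase grid density")
        out[w.index] = sub.pivot_table(index="gene", columns="region",
                                       values="predicted_log2", aggfunc="mean")
    return out


def window_gene_association(
    window_means: dict[int, pd.DataFrame],
    difference: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window Kendall correlation of regional expression with the
    regional group-difference vector; BH-FDR within each window.

    `difference` maps region -> (term - preterm) mean difference for one
    metric. Degenerate difference vectors flag and skip the window.
    """
    if float(np.std(difference)) == 0:
        raise ValueError("degenerate difference vector")
    frames = []
    for widx, mat in window_means.items():
        shared = [r for r in mat.columns if r in difference.index]
        if len(shared) < 4:
            raise ValueError("need >= 4 regions shared with the difference vector")
        d = difference.reindex(shared).to_numpy(float)
        rows = []
        for gene in mat.index:
            expr = mat.loc[gene, shared].to_numpy(float)
            tau, p = kendall_tau(expr, d)
            rows.append({"window": widx, "gene": gene, "tau": tau, "p": p})
        df = pd.DataFrame(rows)
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def significant_window_sets(assoc: pd.DataFrame) -> dict[int, list[str]]:
    return {int(w): sorted(grp.loc[grp["significant"], "gene"])
            for w, grp in assoc.groupby("window")}


def window_cell_enrichment(
    window_sets: dict[int, list[str]],
    catalog: GeneSetCatalog,
    background: list[str],
) -> pd.DataFrame:
    """Hypergeometric ORA of each cell class in each window's significant set.

    Windows with empty significant sets produce all-NA rows with a flag so
    the class x window long table stays heatmap-ready.
    """
    rows = []
    for widx in sorted(window_sets):
        genes = window_sets[widx]
        for cls, set_genes in catalog.sets.items():
            if not genes:
                rows.append({"window": widx, "set_name": cls, "x": np.nan,
                             "N": 0, "K": len(set_genes), "M": len(background),
                             "enrichment_ratio": np.nan, "p": np.nan,
                             "empty_query": True})
                continue
            r = hypergeom_ora(genes, set_genes, background, set_name=cls)
            rows.append({"window": widx, "set_name": cls, "x": r.x, "N": r.N,
                         "K": r.K, "M": r.M,
                         "enrichment_ratio": r.enrichment_ratio, "p": r.p,
                         "empty_query": False})
    return pd.DataFrame(rows)


def associated_in_any_window(window_sets: dict[int, list[str]]) -> list[str]:
    """Union over windows of the per-window significant gene sets."""
    out: set[str] = set()
    for genes in window_sets.values():
        out.update(genes)
    return sorted(out)


def cross_study_overlap(
    de_genes: list[str],
    window_sets: dict[int, list[str]],
    catalog: GeneSetCatalog,
    background: list[str],
) -> pd.DataFrame:
    """Overlap of an external DE list with per-class associated genes.

    For each cell class the query is the DE list and the tested set is
    {genes significant in >= 1 window} intersected with the class markers.
    """
    if not de_genes:
        raise ValueError("empty DE gene list")
    union = set(associated_in_any_window(window_sets))
    rows = []
    for cls, set_genes in catalog.sets.items():
        target = sorted(union & set(set_genes))
        r = hypergeom_ora(de_genes, target, background, set_name=cls)
        rows.append({"set_name": cls, "x": r.x, "N": r.N, "K": r.K, "M": r.M,
                     "enrichment_ratio": r.enrichment_ratio, "p": r.p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
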