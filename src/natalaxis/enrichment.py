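"""Gene-set over-representation analysis and cell-type trajectory embedding.

The ORA statistic is the upper-tail hypergeometric probability of finding x
or more genes from a marker set of size K (in a background of size M) within
a query list of size N,

    p = P(X >= x),  X ~ Hypergeometric(M, K, N),

computed with log-gamma binomial coefficients for numerical stability, with
the enrichment ratio (x/N) / (K/M). One-sided over-representation only.
The FDR family is the collection of sets tested within one call.

The embedding utilities turn per-gene regional trajectory grids into one
unit-norm-per-region, region-concatenated, marker-averaged vector per cell
type, and embed those with UMAP on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .spatial import bh_fdr

log = logging.getLogger(__name__)


# -------------------------------------------------------------------- catalog

@dataclass
class GeneSetCatalog:
    """Named marker-gene sets with class metadata.

    `class_meta` carries per-set lineage (neuronal / glial / other), timing
    (precursor / mature) and free-text source. The unique variant excludes
    genes that appear in more than one set.
    """

    sets: dict[str, list[str]]
    class_meta: dict[str, dict[str, str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self):
        self.sets = {name: sorted(dict.fromkeys(genes))
                     for name, genes in self.sets.items()}
        if self.universe is not None:
            uni = set(self.universe)
            for name, genes in self.sets.items():
                stray = set(genes) - uni
                if stray:
                    raise ValueError(
                        f"set {name!r} contains genes outside the universe: "
                        f"{sorted(stray)[:5]}")

    @property
    def unique_variant(self) -> dict[str, list[str]]:
        counts: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return {name: [g for g in genes if counts[g] == 1]
                for name, genes in self.sets.items()}

    def timing_sets(self) -> dict[str, list[str]]:
        """Pooled precursor / mature gene sets from class timing metadata."""
        out: dict[str, set[str]] = {"precursor": set(), "mature": set()}
        for name, genes in self.sets.items():
            timing = self.class_meta.get(name, {}).get("timing")
            if timing in out:
                out[timing].update(genes)
        return {k: sorted(v) for k, v in out.items() if v}

    def lineage_sets(self) -> dict[str, list[str]]:
        out: dict[str, set[str]] = {}
        for name, genes in self.sets.items():
            lin = self.class_meta.get(name, {}).get("lineage")
            if lin:
                out.setdefault(lin, set()).update(genes)
        return {k: sorted(v) for k, v in out.items()}

    def all_marker_genes(self) -> list[str]:
        return sorted({g for genes in self.sets.values() for g in genes})

    @classmethod
    def from_gmt(cls, path, class_meta=None, universe=None) -> "GeneSetCatalog":
        from .io import read_gmt
        return cls(sets=read_gmt(path), class_meta=class_meta or {}, universe=universe)

    def to_gmt(self, path) -> None:
        from .io import write_gmt
        desc = {name: f"{m.get('lineage', 'na')}|{m.get('timing', 'na')}"
                for name, m in self.class_meta.items()}
        write_gmt(self.sets, path, descriptions=desc)


# ------------------------------------------------------------------------ ORA

@dataclass
class EnrichmentResult:
    set_name: str
    x: int              # overlap count
    N: int              # query size (within background)
    K: int              # set size (within background)
    M: int              # background size
    enrichment_ratio: float
    p: float
    q: float = np.nan


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(x: int, M: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, N) via log-gamma binomials."""
    if x <= 0:
        return 1.0
    hi = min(K, N)
    if x > hi:
        return 0.0
    i = np.arange(x, hi + 1)
    log_terms = _log_binom(np.full_like(i, K), i) \
        + _log_binom(np.full_like(i, M - K), N - i) \
        - _log_binom(np.array(M), np.array(N))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrichment_ratio(x: int, N: int, K: int, M: int) -> float:
    """(x/N) / (K/M); 0 when the overlap is empty, division guarded."""
    if N <= 0 or K <= 0 or M <= 0:
        raise ValueError("N, K, M must be positive")
    if x == 0:
        return 0.0
    return (x / N) / (K / M)


def hypergeom_ora(query: Iterable[str], set_genes: Iterable[str],
                  background: Iterable[str], set_name: str = "") -> EnrichmentResult:
    """One-sided over-representation of `set_genes` in `query`.

    Inputs are deduplicated; query genes absent from the background are
    dropped with a logged count, and the set is intersected with the
    background before counting.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    dropped = q - bg
    if dropped:
        log.info("%d query gene(s) not in background dropped", len(dropped))
    q &= bg
    if not q:
        raise ValueError("query empty after background intersection")
    s = set(set_genes) & bg
    x = len(q & s)
    M, K, N = len(bg), len(s), len(q)
    p = hypergeom_upper_tail(x, M, K, N) if K else 1.0
    ratio = enrichment_ratio(x, N, K, M) if K else 0.0
    return EnrichmentResult(set_name=set_name, x=x, N=N, K=K, M=M,
                            enrichment_ratio=ratio, p=p)


def run_class_enrichment(
    query: Iterable[str] | Mapping[str, Iterable[str]],
    catalog: GeneSetCatalog,
    background: Iterable[str] | str = "all",
    unique: bool = False,
    include_timing: bool = True,
    include_lineage: bool = False,
) -> pd.DataFrame:
    """ORA of one or more query lists against every catalog class.

    `background` may be an explicit gene list, or the keyword "all" /
    "fetal_markers" (the catalog universe, or the union of marker genes).
    Timing (precursor/mature pooled) and optionally lineage sets are tested
    alongside the classes; the BH-FDR family is all sets tested per query
    within this call.
    """
    if isinstance(background, str):
        if background == "all":
            if catalog.universe is None:
                raise ValueError("catalog has no universe for background='all'")
            bg = list(catalog.universe)
        elif background == "fetal_markers":
            bg = catalog.all_marker_genes()
        else:
            raise ValueError(f"unknown background label {background!r}")
    else:
        bg = list(background)

    sets = dict(catalog.unique_variant if unique else catalog.sets)
    if include_timing:
        sets.update({f"timing:{k}": v for k, v in catalog.timing_sets().items()})
    if include_lineage:
        sets.update({f"lineage:{k}": v for k, v in catalog.lineage_sets().items()})

    queries = query if isinstance(query, Mapping) else {"query": query}
    frames = []
    for qname, qgenes in queries.items():
        rows = []
        for name, genes in sets.items():
            r = hypergeom_ora(qgenes, genes, bg, set_name=name)
            rows.append({
                "query": qname, "set_name": name, "x": r.x, "N": r.N,
                "K": r.K, "M": r.M, "enrichment_ratio": r.enrichment_ratio,
                "p": r.p,
            })
        df = pd.DataFrame(rows)
        df["q"] = bh_fdr(df["p"].to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -------------------------------------------------------- cell-type embedding

def build_celltype_trajectory_matrix(
    grids: pd.DataFrame,
    catalog: GeneSetCatalog,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cell-type x (region * timepoint) matrix of averaged marker trajectories.

    `grids` is the long trajectory table (gene, region, age, predicted_log2).
    Per gene and region the trajectory is scaled to unit Euclidean norm, the
    per-region rows are concatenated in fixed region order, and the
    concatenated vectors are averaged over the cell type's markers. Cell
    types with no surviving markers are dropped with a warning.
    """
    wide = grids.pivot_table(index=["gene", "region"], columns="age",
                             values="predicted_log2")
    regions = list(regions or sorted(grids["region"].unique()))
    n_t = wide.shape[1]

    gene_vectors: dict[str, np.ndarray] = {}
    for gene in wide.index.get_level_values("gene").unique():
        sub = wide.loc[gene]
        if not set(regions) <= set(sub.index):
            continue
        parts = []
        for r in regions:
            v = sub.loc[r].to_numpy(float)
            nrm = np.linalg.norm(v)
            parts.append(v / nrm if nrm > 0 else v)
        gene_vectors[gene] = np.concatenate(parts)

    rows = {}
    for cls, genes in catalog.sets.items():
        vecs = [gene_vectors[g] for g in genes if g in gene_vectors]
        if not vecs:
            log.warning("cell class %s has no markers with fitted grids; dropped", cls)
            continue
        rows[cls] = np.mean(vecs, axis=0)
    if not rows:
        raise ValueError("no cell class has marker trajectories")
    cols = [f"{r}:t{i}" for r in regions for i in range(n_t)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def embed_celltypes(matrix: pd.DataFrame, seed: int = 0,
                    n_neighbors: int = 5, min_dist: float = 0.1) -> pd.DataFrame:
    """2D UMAP embedding (Euclidean metric), deterministic given the seed."""
    import umap

    n_neighbors = min(n_neighbors, len(matrix) - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric="euclidean",
                        random_state=seed)
    coords = reducer.fit_transform(matrix.to_numpy(float))
    return pd.DataFrame(coords, index=matrix.index, columns=["umap1", "umap2"])
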