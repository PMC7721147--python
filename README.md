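# natal-axis

Imaging–transcriptomics of the neonatal cortical principal axis.

Regional variation in neonatal cortical MRI metrics — cortical thickness,
T1w/T2w contrast, FA, MD, fICVF and ODI measured in 11 cortical regions —
can be summarised by a single principal axis that separates primary
sensorimotor from higher-order association cortex. This package implements,
as a tested and reusable pipeline, the analysis chain that links that axis to
prenatal cortical gene expression:

1. **Principal imaging axis** — hemisphere-averaged regional metrics are
   cleaned with a modified z-score cutoff (|0.6745·(x − median)|/MAD > 3.5),
   z-scored per metric over the pooled term cohort, averaged into a group
   region × metric matrix *X*, and decomposed by eigendecomposition of its
   covariance: loadings *W<sub>L</sub>*, region scores
   *T<sub>L</sub> = XW<sub>L</sub>*. Each individual *s* (term or preterm) is
   projected as *T<sub>Ls</sub> = X<sub>s</sub>W<sub>L</sub>*, with the
   fraction of matrix energy along PC1,
   ‖X̃<sub>s</sub>w₁‖²∕‖X̃<sub>s</sub>‖²<sub>F</sub>, as a per-individual
   summary.
2. **Expression trajectories** — per gene, Winsorised (5th/95th centile)
   log2 RPKM is modelled as *y ∼ f(v) + Xβ + Zb*: a natural cubic spline of
   age with 4 knots evenly spaced over the age span, fixed effects of sex and
   RIN, and a random intercept per specimen, fitted by maximum likelihood and
   compared with a nested linear-age model via AIC/BIC.
3. **Spatial association** — residuals of the nonlinear model (which has no
   region term) retain the spatial signal; per gene they are correlated with
   the regional PC1 score (Kendall's τ-b), corrected across genes by
   Benjamini–Hochberg FDR, and split into PC+ and PC− sets. A
   gene-resampling permutation test validates set-level regional fold
   changes.
4. **Cell-class enrichment** — one-sided hypergeometric over-representation,
   p = P(X ≥ x) for X ∼ Hypergeom(M, K, N), with enrichment ratio
   (x/N)/(K/M), applied to marker-gene classes, pooled precursor/mature
   timing sets, and cross-study DE overlaps; plus a UMAP embedding of
   unit-normalised, region-concatenated cell-type trajectories.
5. **Tissue maturity** — expression corrected for sex, RIN and specimen
   identity (age retained) feeds a linear-kernel SVR (C = 10) trained
   leave-one-specimen-out on specimen-mean profiles vs age, predicting an
   age for each held-out regional profile; gene-bootstrap CIs and an
   age-permutation test for the development of the maturity–axis
   correlation (statistic: r² of per-specimen Pearson r regressed on age).
6. **Group comparison** — per metric, a mixed model
   value ∼ age + sex + group + PC1 + group:PC1 + (1|participant) with ML
   nested-model AIC/BIC, marginal means and Cohen's d against the total SD;
   an ANCOVA on per-individual variance explained; and correlation of
   regional term−preterm differences with the axis.
7. **Time-windowed association** — region-specific trajectory smooths are
   averaged within ten equal windows spanning 160–260 postconceptional days
   and correlated per window with the regional group-difference profile,
   with per-window FDR, cell-class enrichment, and cross-study DE overlap.

The cohort-scale inputs this analysis was designed for are restricted-access,
so the package ships a first-class synthetic-data module
(`natalaxis.syndata`) that generates imaging cohorts, expression atlases,
marker catalogs and DE lists with planted, recorded ground truth — every
stage of the pipeline is exercised and tested against what was planted.

## Worked example

```python
import pandas as pd
from natalaxis import syndata, trajectories as traj, spatial

expr, truth = syndata.generate_expression_atlas(
    n_specimens=16, n_genes=150, n_planted_pos=10, n_planted_neg=10, seed=42)
pre = traj.preprocess_expression(expr, min_obs=10)
fits = traj.fit_all_genes(pre, fit_linear=False)
residuals = traj.age_corrected_expression(fits, pre)
assoc = spatial.correlate_genes_with_axis(
    residuals, pd.Series(truth.axis_region_scores), alpha=0.05)
```

Running this (`python examples/02_gene_axis_association.py`) prints:

```
genes tested: 150; significant at FDR<0.05: 20 (10 PC+, 10 PC-)
planted genes recovered: 20/20
false discoveries: 0

mean tau of PC+ genes: 0.323
```

All 20 planted spatially graded genes are recovered with no false
discoveries, and the mean τ of the discovered PC+ set sits at the planted
population value (≈0.3). The other scripts in `examples/` walk through each
capability the same way: the principal axis (01), cell-class enrichment (03),
tissue-maturity prediction with permutation inference (04), term/preterm
group comparison (05), time-windowed association (06), and the full
orchestrated pipeline (07).

## Command line

A thin CLI wraps the library for shell use:

```bash
natal-axis simulate --out data/ --seed 1        # synthetic input tables
natal-axis axis --metrics data/metric_table.tsv --out results/
natal-axis run --config cfg.yaml                # full pipeline + run report
```

`natal-axis run` executes all eight stages with per-stage seeds from the
YAML config and writes plain TSV/JSON outputs plus a machine-readable
`run_report.json`; reruns with the same config are byte-identical.

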