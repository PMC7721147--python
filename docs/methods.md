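# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `natal-axis` pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Principal imaging axis

Regional metric values are averaged across hemispheres (single-hemisphere
entries pass through with a warning), then cleaned per (region, metric) with
the modified z-score rule |0.6745·(x − median)|/MAD > 3.5; a zero MAD flags
nothing. The 0.6745 consistency constant is the standard convention that
makes the modified z-score comparable to a normal z-score, matching the 3.5
cutoff's usual calibration.

**Z-scoring convention.** Each metric is z-scored over the pooled term-cohort
(participant × region) observations, and those term-derived means/SDs are
frozen and reused for every individual — including preterm infants — so both
groups live on one scale. Whether to z-score per metric across the pooled
observations or within participant is genuinely open; the pooled convention
is the package default because the term/preterm comparison requires a common
scale. The within-participant alternative can be built from
`build_group_matrix` on per-participant slices but is not a config switch.

The group region × metric matrix (term average of z-scores) is
column-centred and decomposed by `numpy.linalg.eigh` of its covariance;
variance fractions are eigenvalues over the trace. Sign convention: the
loading of maximal magnitude in each component is positive (the sign of an
eigenvector is otherwise arbitrary). Individuals are centred with the group
column centres before projection so scores are comparable; per-component
variance explained is ‖X̃w_j‖²/‖X̃‖²_F on the centred matrix, which sums to
1 over a complete basis. Projection requires at least 6 regions; missing
regions are dropped with a logged count.

## Expression trajectories

Per-gene preprocessing Winsorises RPKM at the 5th/95th percentile (numpy's
linear-interpolation percentile) before log2; if clamping leaves
non-positive values, the smallest positive clamped value is added as a
pseudocount (logged). All-zero genes are excluded.

The nonlinear model is a natural cubic spline of age with **4 knots evenly
spaced across the observed span** — boundary knots at the endpoints, two
interior knots — built with patsy's `cr()` basis with explicit bounds. With
4 knots the basis has 4 degrees of freedom and spans both the intercept and
the linear trend, so the linear-age comparison model (intercept + age) is
exactly nested; the nonlinear model's maximised likelihood therefore
dominates the linear one, and ΔBIC − ΔAIC = Δk(ln n − 2) with Δk = 2. Fixed
effects of sex (F=0, M=1) and RIN (centred at the sample mean) plus a random
intercept per specimen complete the model, fitted by **maximum likelihood**
(not REML) with statsmodels MixedLM, because AIC/BIC comparisons across
fixed-effect structures require ML. Constant covariates (e.g. a single-sex
subset) are dropped from the design with a zero coefficient rather than left
to make it singular.

Optimisation uses BFGS first (fast and reliable here), then statsmodels'
default sequence, then Powell; a gene whose fits do not converge is excluded
with a warning. Rows are canonicalised (sorted by specimen and region)
before fitting so results are invariant to input row order. When the
random-effect variance collapses to the boundary the predicted intercepts
are zero and the fit is effectively fixed-effects.

Age-corrected expression is the residual y − (f(age) + Xβ + Zb) of this
region-free model: regional signal deliberately survives into the residuals.
The model comparison reported per gene is region-agnostic linear vs
nonlinear; whether region terms belong in either comparison model is
ambiguous in principle, and this implementation keeps both models
region-free so the comparison isolates the age trend.

Region-specific trajectories come from a second model with a separate spline
block per region (same knots) plus the shared sex/RIN effects. Grids are
evaluated at reference covariates — sex balanced at 0.5, RIN at the sample
mean — at evenly spaced ages strictly within the fitted span (no
extrapolation).

## Spatial association

Kendall's τ-b (tie-adjusted) via scipy, with exact small-sample p-values
where scipy's exact path applies and the tie-corrected normal approximation
otherwise; an all-tied vector degenerates to τ = 0, p = 1 with a flag. The
τ-b variant is used because residual RPKM is continuous and ties are rare,
so variants agree. By default every (specimen, region) sample enters one
correlation per gene against the PC1 score of its region; a `region_mean`
mode aggregates to region means first. BH-FDR across genes (statsmodels);
PC+/PC− labels at q < α split by the sign of τ.

The fold-change permutation test resamples **gene sets** (not region
labels), since the region groups are fixed by anatomy; the statistic is the
set mean of per-gene A/B regional expression ratios and p uses the add-one
convention (1 + #{null ≥ obs})/(n_perm + 1), so p is never 0 and equals 1
when the set is the whole background.

## Enrichment

The over-representation p-value is the upper hypergeometric tail
P(X ≥ x), computed by summing exp(log-gamma binomial terms) with logsumexp —
numerically stable for large backgrounds; scipy's `hypergeom.sf` serves as an
independent cross-check in the tests, never as the implementation. Only the
one-sided over-representation test is provided. Queries are deduplicated and
intersected with the background (dropped genes logged); marker sets are
intersected with the background before counting. The FDR family is the sets
tested within one call — classes plus pooled precursor/mature timing sets
(and optionally lineage sets); cross-call corrections are the caller's
responsibility. The precursor/mature test pools genes across classes of the
same timing annotation, with the per-class breakdown emitted alongside.

Cell-type trajectory vectors: per gene and region the dense grid is scaled
to unit Euclidean norm (shape, not level), concatenated over regions in a
fixed order, and averaged over the type's markers; UMAP (Euclidean,
n_neighbors = 5, min_dist = 0.1, fixed random_state) gives the 2D embedding.
The hyperparameters are configuration; nothing in the analysis depends on
them beyond qualitative cluster separation, which the tests check with a
within- vs between-class distance comparison.

## Tissue maturity

Age-retained correction subtracts βsex·sex + βrin·rin + b_specimen but keeps
f(age): the age signal is the predictor of interest. The LOO-SVR uses a
linear kernel with C = 10.0 and ε = 0.1 **on the standardized target**;
features and targets are standardized with training-fold statistics only, so
no information leaks from the held-out specimen (a corruption test verifies
the held-out specimen's predictions are unaffected by its own training row).
Constant training features are dropped in-fold; if all features are
constant, predictions collapse to the training-age mean (the model
intercept).

Bootstrap CIs resample gene columns with replacement, rerun the whole LOO
pipeline, and take 2.5/97.5 percentiles; the point estimate is the bootstrap
mean. The maturity–axis statistic is r² of the regression of per-specimen
Pearson r (predicted regional age vs PC1 score) on specimen age; the null
permutes the assignment of specimen-mean profiles to ages during training
and reruns the full LOO pipeline per permutation, **without** nested gene
bootstrapping inside each permutation (one full-gene model per permutation)
for tractability. Permutation p uses the add-one convention. Ages are
postconceptional days throughout.

## Group comparison

Per metric: value ∼ age_at_scan + sex + group + PC1 + group:PC1 with a
participant random intercept, ML fit; per-term tests are Wald F = (β/SE)²
against F(1, n − k). Nested comparison drops both birth-status terms.
Marginal means are evaluated at the pooled age mean, sex balanced 50/50, and
the PC1 score averaged over the 11 regions, with delta-method 95% CIs.
Cohen's d is the marginal mean difference over the total SD
√(σ²_participant + σ²_resid) — the mixed-model analogue of a classical d;
no standard convention exists for mixed models, so the choice is documented
here. A singular random-effect fit falls back to OLS with a warning.

The ANCOVA on per-individual variance explained uses OLS with type-II F
tests (variance_explained ∼ group + age + sex + group:age). The response is
the per-individual PC1 variance-explained fraction defined above — the
natural reading of "variance in an individual's imaging data explained by
the axis".

Regional difference profiles correlate the 11 per-region (term − preterm)
mean differences with PC1 scores per metric (Pearson), BH-FDR across the 6
metrics; a difference vector whose SD is below 1e-12 of its scale is flagged
degenerate with r = 0, p = 1.

## Time windows

Ten equal half-open windows cover [160, 260) postconceptional days (the last
window closed); the convention is arbitrary and stated here. Window means
average the dense trajectory grid points falling in each window, with the
grid density set to ≥ 10 points per window so the mean of a linear
trajectory matches its midpoint value to < 0.5% relative error. Per window,
each gene's regional profile is correlated (Kendall, exact p at 11 untied
pairs) with the regional group-difference vector, with FDR **within** each
window — the ten windows are reported as ten separate analyses, matching
the per-window reporting of the time-resolved design; cross-window
correction is the caller's concern. "Associated in at least one window" is
the union of per-window significant sets, and the cross-study test runs ORA
of an external DE list against that union intersected with each class's
markers. Kendall is used for consistency with the axis association stage.

## Synthetic-data generator

The generators are the package's study conditions, not fixtures.

**Imaging cohort** (defaults: 292 term + 64 preterm, 11 regions, 6 metrics,
both hemispheres): each observation is
μ_m + s_m·(a_p·s_r·w_m + preterm·(shift_m + axis_m·s_r) + age-slope + ε),
with unit-norm metric loadings w, fixed region scores s_r placing primary
sensorimotor regions at one extreme and association cortex at the other
(configuration values, not data), participant axis weights a_p ∼ N(1, 0.25),
hemispheric noise ε ∼ N(0, 0.35) inflated ×1.5 off-axis for preterm infants
(so the axis explains less of their variance), and metric-native means and
scales (thickness in mm, MD in μm²/ms, the rest ratios). The preterm shift
magnitudes are sized to produce Cohen's d of roughly 1.6 (T1w/T2w, deficit),
−1.2 (MD), −0.65 (thickness), 0.55 (FA), 0.3 (fICVF) and ~0 (ODI) — the
ordering and rough magnitude of the reported clinical pattern — and the
axis-aligned component makes the T1w/T2w deficit largest at the
primary-cortex end, so the regional difference profile anticorrelates with
the axis. Ages: term birth ~N(40, 1.2) weeks, scan shortly after; preterm
birth ~N(32, 3.9) weeks, scanned at term-equivalent age. No empirical noise
magnitudes are published for the summary tables; the defaults above are the
package's own choice of a realistic regime and are config, not claims about
any cohort.

**Expression atlas** (defaults: 16 specimens aged 84–259 pc days — 21 over
56–380 in the pipeline demo, covering the extended age range the maturity
model needs; first/last specimens pinned at the range endpoints so fitted
spans cover the analysis window): per gene,
signal = f_g(age) + β_sex·sex + β_rin·(rin − mid) + b_s + δ_g·s_r + ε on the
log2 scale, RPKM = 2^signal (strictly positive). f_g is a cubic polynomial
in scaled age with random coefficients — deliberately inside the span of the
4-knot natural cubic spline, so recovery tests run under a well-specified
model. RIN ~ U(8, 10), sex ~ Bernoulli(0.5), b_s ~ N(0, 0.3), ε ~ N(0, 0.5).
δ_g is nonzero only for planted genes; its default magnitude is derived from
a target population Kendall τ (default 0.3) through Greiner's relation
τ = (2/π)·asin(ρ), inverted for the effect size given the noise SD and the
region-score spread. Each specimen drops regions independently at rate 0.11
(≈ 9.8 of 11 sampled) but never below 3. Two optional planted effects:
`maturity_gradient` evaluates trajectories at an effective age shifted by
−score_r·(age − lo)/(hi − lo)·gradient days (a maturity–axis anticorrelation
growing over gestation), and `spatial_window` confines δ to an age interval
with linear ramps (late-onset spatial patterning).

**Catalog**: ten cell classes with lineage (neuronal/glial/other) and timing
(precursor/mature) annotations. Base sets are disjoint; classes with a
planted fraction draw that share of markers from the planted genes, classes
without one sample uniformly from the unused universe so their planted
overlap follows the hypergeometric null (verified by simulation).
`overlap_rate` then injects cross-class sharing for the unique-variant
logic. **DE list**: per-class fractions drawn from the catalog sets, the
remainder uniform; composition recorded.

All generators are fully determined by their integer seed (byte-identical
regeneration is tested), and every planted quantity is recorded in a
`SyntheticTruth` object.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions, metric-specific noise covariance, batch/technical
structure in expression (the real inputs arrive batch-corrected),
gene–gene co-expression beyond the shared axis signal, and count-level
sampling noise (RPKM is treated as log-normal). Passing tests therefore show
the estimators recover the planted generative structure at realistic sizes
and noise levels — not that they are robust to those unmodelled features of
real data.

## Problem sizes and runtime choices

The default test and acceptance runs use reduced sizes chosen as desk-scale
versions of the study design: cohorts of 40–150 term + 15–50 preterm,
atlases of 150–500 genes with 12–50 planted, 16–21 specimens, n_perm of
99–500 and n_boot of 20–200 where the full-scale constants are 5,000–10,000
and 1,000. The full-scale constants remain the config defaults
(`RunConfig`). Calibration checks use binomial 99% bounds appropriate to
their replicate counts.

## Known limitations

- The mixed-model per-term tests are Wald F approximations, not
  likelihood-ratio tests; at the cohort sizes used they agree closely.
- The windowed stage fits region-specific smooths only for catalog marker
  genes (capped by `max_region_fit_genes`) — the enrichment analysis only
  consumes marker genes, but the per-window gene universe is correspondingly
  the marker subset.
- No spatial-autocorrelation-preserving null (spin test) is provided for the
  gene–axis association; the permutation and FDR machinery treats regions as
  exchangeable units.
- UMAP determinism is per-seed; embeddings across library versions may
  differ while preserving cluster structure.
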