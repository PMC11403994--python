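# Methods

## Scaling model

Protein "concentration" is proxied by mean per-pixel stain intensity
over a 2-D segmented compartment (whole cell, nucleus, or cytoplasm);
volume is not modelled. The concentration–size relationship is a power
law, `[Y] = a·A^b`, fitted by ordinary least squares on
`log2[Y] = log2(a) + b·log2(A)` over single cells (not bin means; a
binned display profile is available separately). Base-2 logarithms are
used throughout so intercept differences read directly as fold changes;
the slope is base-invariant. Abundance is integrated intensity
(mean × compartment area), and when the regressor is the compartment's
own area the abundance slope equals the concentration slope plus one
exactly — this OLS identity is asserted to 1e-9 in the tests and serves
as an internal consistency check on any table.

Degenerate inputs: a zero-variance response returns `b = 0`, intercept
equal to the constant, and `r² = 1` by convention, so constant synthetic
channels flow through batch reports rather than erroring; zero-variance
areas raise, since the slope is undefined.

### DNA stratification and fold factor

Cells are split at the per-line *median* integrated DNA-stain intensity;
ties go to the low bin (a deterministic reading of "either side of the
median"). The concentration step between bins is reported as
`2^Δ`, where `Δ` is the difference of the two fitted lines evaluated at
a common reference size — the geometric mid-size of the fit windows.
When the two slopes agree this equals the raw intercept difference
`log2(a_high) − log2(a_low)`; with independently fitted slopes,
evaluating at unit area would extrapolate ~9 log2 units outside the
measured range and amplify slope noise by that lever arm (a ±0.01 slope
error becomes a ±10% fold error), so the in-window evaluation is the
estimator the package reports.

### Size window

Fits are restricted to cells within k = 3 standard deviations of the
mean area (per line × DNA bin), a closed interval clipped below at
zero, computed on raw areas by default (a log-area switch is provided).
The clip is iterated to a fixed point (monotone sigma-clipping): the
retained set is then self-consistent — every kept cell lies within k SD
of the kept cells' own moments — which makes the filter idempotent, a
property a single pass cannot have (trimming shrinks the SD, so a second
pass would always remove a little more). The first iteration is exactly
the plain mean ± 3 SD rule; on the default synthetic populations the
iteration converges in 2–4 passes and removes ~2% of cells.

### Other exclusion rules

Neighbour fraction (fraction of perimeter touching neighbours) strictly
greater than 0.7 is excluded; the boundary is kept. The rule is applied
before nuclear-YAP analyses by default and is optional elsewhere.
Mitotic cells are dropped by flag when available, otherwise by jointly
exceeding both a Hoechst-mean and a Hoechst-max threshold (condensed
chromatin is both brighter and more peaked; the conjunction avoids
removing bright interphase nuclei).

## Cell-cycle calling

Classification is sequential and never sees YAP features or (except post
hoc) integrated DNA: (1) mitotic cells set aside; (2) PCNA-negative
nuclei → G0; (3) PCNA+/CCNA2− → G1; (4) PCNA+/CCNA2+ cells in the
lowest quartile of CCNA2 (per line) → early S; (5) the remainder split
S vs G2 by PCNA texture ("spotty" vs "smooth"). Positivity thresholds
default to per-line Otsu splits because absolute intensities are
instrument-specific; both are overridable. The spotty/smooth rule is a
Fisher linear discriminant trained from labelled examples — closed-form,
deterministic, hyper-parameter-free — standing in for the interactively
trained linear classifiers of screening software; a tiny ridge
(1e-9 × mean within-class variance) keeps the direction defined for
perfectly separated inputs. Mean integrated DNA per called stage is
checked post hoc for the ordering G1 < S < G2.

Stage × size comparisons use area-quartile bins and two-sided
Wilcoxon rank-sum tests (exact for small untied samples; two identical
constant samples are defined as p = 1, where the tie correction
degenerates). No multiple-testing correction is applied; contrasts with
fewer than 3 cells on a side are skipped.

## Excess phosphorylation and PLSR

A phosphopeptide's abundance trivially tracks its parent peptide, so
each phosphopeptide is regressed (OLS) on its matched total peptide
across cell lines and the *residual* — "excess phosphorylation" — is the
predictor carried forward. "Scaled" abundances are z-standardized per
peptide across lines before the fit (removing depth/loading differences
between lines); an unscaled option exists. Matching is per-peptide
rather than pooled per-gene: the finer, well-defined unit. Residuals sum
to zero and are uncorrelated with the totals by the normal equations;
both are asserted on every run. Zero-variance totals yield centred
phospho values, flagged.

PLS1 is fitted by NIPALS-style sequential deflation with per-component
unit-norm weight vectors; predictors are z-scored and the response
centred/scaled internally. `SSY_f = q_f²·t_f't_f` records the response
sum of squares captured by component f. The component count is chosen by
cross-validation with folds capped at the sample count (leave-one-out
for the typical 8-line panel, with a fixed fold assignment under the
given seed otherwise), keeping components while each improves the CV MSE
by at least 5% relative and stopping at the first that does not. A model
whose CV error is no better than 90% of the mean-only baseline is
flagged low-signal.

VIP uses the standard Wold arrangement,
`VIP_j = sqrt(J · Σ_f SSY_f·w_jf² / SSY_total)`, under which
`Σ_j VIP_j² = J` identically — so VIP > 1 ("more important than
average") is the hit threshold, the boundary itself excluded. The
association sign comes from the PLSR regression coefficient vector.
Hits are exported ranked by VIP for downstream enrichment tools.

## The synthetic-data generator

The generator emulates the *statistical structure* the analyses consume,
not images: it is the ground truth against which parameter recovery,
classification accuracy, and hit calling are measured.

**Cell tables.** Areas are lognormal (log2 mean 9.2 ≈ 600 µm², log2 SD
0.5, putting ±3 SD at an 8-fold size range). Each channel's mean
intensity is `a·A^b` times multiplicative lognormal noise with median 1
(CV 0.2 by default), so the planted power law is unbiased in log space;
with the default noise the single-cell fits give R² ≈ 0.3–0.55 across
the planted b range, matching what well-behaved immunofluorescence
channels show. Integrated intensity is mean × compartment area exactly.
DNA content is a two-mode lognormal mixture (modes 1:2, CV 0.10) with
the mode placed by cell-cycle stage (G0/G1 low; early S 15% and S 60%
of the way up on a geometric scale; G2/M high). The DNA-bin amplitude
factor (default 1.4 for YAP channels, in the observed 1.3–1.6 range) is
planted on the observable bin the analysis uses — cells above the
population median DNA — which makes fold-factor recovery well-posed
under the median-split estimator for any stage mix. Nuclear area is
`0.25·A^γ` with γ = 1 and 15% noise, capped at 0.9·A; the cytoplasmic
compartment is the remaining area (real pipelines often use a
perinuclear ring — a documented simplification). Neighbour fractions are
Beta(2, 5); mitotic (2%) and border (5%) cells get flags and condensed-
chromatin Hoechst signatures. Stage marker features (PCNA mean, CCNA2
mean, and a scalar "spottiness" texture surrogate for the multi-feature
PCNA texture panel) are separable per-stage Gaussians whose means are
placed so the procedure's own thresholds (Otsu splits, first-quartile
CCNA2) fall in the designed valleys; the default stage mix
(G0 0.10, G1 0.40, earlyS 0.125, S 0.15, G2 0.225) sets early S to one
quarter of the PCNA+/CCNA2+ pool, consistent with the quartile rule.

**Phospho panels.** Totals are lognormal, low-rank in log space: four
latent programs shared across peptides, constructed orthogonal to the
response in sample (bulk protein abundance does not track the readout).
Phospho = α + β·total + excess, where the excess shares the same
response-orthogonal factors (independent loadings, SD 1) plus
idiosyncratic noise (SD 0.1); the planted informative peptides (10 of
200 by default) add ±3 SD of the standardized response. The low-rank,
response-orthogonal construction matters: with only 8 lines, the
per-peptide correction otherwise injects chance correlations of order
`|corr(excess, total)|·|corr(total, response)| ≈ 0.14` into null
peptides, and no amount of planted signal can then keep the VIP > 1
false-positive count low. Abundances are floored at a tiny positive
value (never reached under defaults).

**What passing tests do and do not show.** The generator's noise is
homoscedastic in log space, stages are conditionally Gaussian and
independent of size, and the panel's nuisance structure is exactly
low-rank — real data have size-dependent segmentation errors, texture
features far richer than one scalar, batch effects, and missing values
(TMT reporter-ion statistics and LC-MS missingness are explicitly not
emulated). Recovery under these conditions validates the estimators and
the plumbing, not robustness to those real-world pathologies.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.Generator` seeds; identical
configs reproduce tables bit for bit, and the pipeline serializes CSVs
at 9 significant digits so reruns are byte-identical. The test suite and
acceptance script use 2,000–10,000 cells per population and the
8 × 200 panel — sizes at which the recovery tolerances (|b̂ − b| ≤ 0.05,
fold factor ± 0.05, ≥ 90% stage agreement, median ≥ 8/10 planted hits
over 20 seeds) have comfortable margins while the whole suite runs in
seconds.

## Known limitations

Only the windowed linear fit is implemented; curvature of b across the
full size range is not quantified. No bootstrap confidence intervals on
b and no mixed-effects pooling across lines. The cytoplasm is
area-complement rather than a perinuclear ring. Separate PLSR models are
fitted per response variable (e.g. nuclear concentration and N/C ratio),
not a joint multi-response model.
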