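# Methods

## Model and procedure

The pipeline analyzes a feature × sample matrix of raw MS intensities from a
two-group design (WT vs KO; the contrast is always KO − WT). Stages run in a
fixed order: per-platform median normalization → log transform → per-feature
mean imputation → per-feature moderated t-test → BH adjustment →
z-transformation → pathway rotation test → BH over pathways → summaries.

### Preprocessing

*Normalization.* Within each acquisition platform (RP-UPLC positive,
RP-UPLC negative, GC-MS), each sample's present values are multiplied by a
single factor so that its median equals the platform's median of per-sample
medians. The alternative reading of "group-median" normalization — scaling
each genotype group to its own median — would cancel exactly the group
effects the analysis estimates, and is not implemented. Factors are recorded
in the provenance output.

*Log transform.* Base 2 by default so downstream group-mean differences are
log2 fold changes directly comparable to published fold-change tables. A
configurable pseudocount handles zero intensities (default 0; zeros raise).

*Imputation.* Each missing cell is replaced by the mean of its feature's
present values across **all** samples. The grand mean (rather than the
group mean) is the conservative choice: it pulls an imputed feature's
apparent group difference toward zero rather than reinforcing it.
Imputation runs after the log transform. Imputed coordinates are flagged in
the provenance record.

The composed preprocessing map is exactly idempotent on complete data.
With missing data it is idempotent only up to the per-sample median shift
that the imputed values induce on re-normalization — in practice negligible
at realistic missingness but not exactly zero, which is why the invariant is
tested on complete matrices.

### Moderated two-group test

Per feature: logFC = mean_KO − mean_WT, average expression = grand mean,
pooled within-group variance s² with d = n₁ + n₂ − 2 df. The variance prior
is scaled inverse-χ²(d₀, s₀²), estimated once per run by moment matching on
e = log s² − ψ(d/2) + log(d/2) (ψ the digamma function): d₀ solves
ψ′(d₀/2) = var(e) − mean ψ′(d/2) via a Newton inversion of the trigamma
function, and s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)). When the observed
spread of log variances does not exceed the χ² sampling floor, d₀ = ∞ and
s₀² is the plain mean of the variances (complete shrinkage; the reference
distribution becomes normal). Prior estimation requires ≥ 10 features.

The moderated t replaces s² with the posterior (d₀s₀² + d·s²)/(d₀ + d) and
gains d₀ df. Setting d₀ = 0 (or disabling shrinkage) recovers the ordinary
pooled t-test exactly; d₀ = ∞ recovers a normal test with variance s₀².
p-values are two-sided; direction is carried by the sign of logFC.

*Multiple testing.* BH step-up, implemented directly (stable sort, so the
result is independent of input order). In the pipeline, the per-metabolite
adjustment runs over m = the uniquely identified metabolites tested in the
run; m is written to the manifest and log, since adjusted p-values are only
comparable given m.

*z scores.* z = Φ⁻¹(F_t(t̃; d + d₀)), evaluated on the smaller tail and
reflected so large |t̃| does not saturate at double precision; |z| is
clamped at 37. z and t̃ have identical two-sided p-values to at least six
digits over the range used.

### Pathway rotation test

Pathway sets are intersected with the uniquely identified, tested
metabolites; coeluting (multi-compound) features never enter a set, and
sets with fewer than 3 members are discarded (both counts logged). The
deregulation statistic is the arithmetic mean of member z scores; its sign
gives the direction call, and members with |z| > √2 (strict) are counted as
up/down contributors.

Each feature's n-vector is reduced to d + 1 coordinates: an effect
coordinate u = logFC/√(1/n₁ + 1/n₂) and d residual coordinates in a fixed
orthonormal basis (QR of the complement of the intercept/contrast plane),
satisfying ‖r‖²/d = s² and u/√(s²) = unmoderated t. A rotation draws one
unit vector ρ uniformly on the sphere in R^(d+1) — one draw per rotation,
shared across all features, which preserves the inter-metabolite
correlation structure — and produces rotated effects u* = ρᵀy and variances
s*² = (‖y‖² − u*²)/d, pushed through the same moderation and z-transform
with the prior frozen at its observed-data estimate (re-estimating per
rotation would be costly and changes the null being sampled).

p-values use the add-one convention: p_up = (#{S* ≥ S_obs} + 1)/(B + 1)
(ties count as exceeding; conservative), p_down analogously, directional
p = min(1, 2·min(p_up, p_down)). A "mixed" alternative (|S*| ≥ |S_obs|) is
available but non-default. B defaults to 9999, floor 1/(B+1); B ≥ 99 is
enforced. For a singleton set without moderation the rotated statistic is
exactly t_d-distributed, so the rotation p converges to the parametric
two-sided t p — the calibration check the test suite runs at B = 10⁵.
The Monte-Carlo standard error of the directional p is 2·√(p₁(1−p₁)/B)
with p₁ the one-sided exceedance probability (the doubling doubles the
error too).

### Summaries

PCA treats samples as observations and features as variables, centered but
not scaled (intensities are already on one log scale); components come from
a full SVD with a deterministic sign convention (largest-magnitude loading
positive). Volcano tables use strict adjP < α (α = 0.05). Heatmap
clustering standardizes rows (z-score per feature; constant rows raise),
then average-linkage on Euclidean distances for both axes — the
linkage/distance choice is a package decision, configurable, since several
conventions are common. Phenotype statistics use divisor-n SDs and the
pooled-variance (not Welch) two-sided Student t-test; both conventions were
fixed by checking which reproduces the published per-mouse summary table
(divisor n−1 and Welch do not).

Metabolite-count summaries use strict adjP < 0.05 while pathway counts use
adjP ≤ 0.05; both comparators are exposed because published usage mixes the
two phrasings.

## Synthetic data generator

Defaults emulate the study's structure: 6 + 6 samples; 600 features split
(0.49, 0.48, 0.03) across the three platforms (a `paper_scale_spec` preset
uses the study's 4143/283/32 counts); 28% of features annotated, 11% of
those coeluting (2–3 compound names); 40 pathways of size 3–20 drawn from
the unique compounds; log2 grand means uniform on [11, 27] (the observed
average-expression range); variances s₀²·d₀/χ²_{d₀} with (d₀, s₀²) =
(4, 0.04); half the pathways deregulated with a pathway-level shift of
magnitude uniform on [0.5, 2.5], random sign, plus per-metabolite jitter
(SD 0.3) — effects are assigned at the pathway level because the analysis
targets coherent pathway shifts; 3% of cells missing completely at random
(MCAR; chosen over intensity-dependent missingness for testability).
Generation is a pure function of the spec, including the seed.

Default pathways may overlap (as real pathway databases do); when a shared
metabolite falls in two deregulated pathways the first (in name order)
determines its shift. A `disjoint_pathways` option partitions compounds
instead — calibration and power checks use it, because with overlap a
nominally null pathway can contain genuinely shifted metabolites and the
notion of a "false positive" blurs. m = 600 (not 4143) keeps the default
test suite fast; statistical conclusions at 600 transfer because every
per-feature computation is independent of m except prior estimation, which
only tightens with m.

What the generator does **not** emulate: chromatographic drift and batch
effects, intensity-dependent (MNAR) missingness under the default,
platform-specific noise profiles, correlated features within pathways
beyond the shared mean shift, and annotation errors. Passing tests
therefore certify the statistical machinery under the stated hierarchical
model, not robustness to those real-data artifacts.

One interaction worth knowing: with only a few hundred features per
platform, the median-normalization factors carry estimation noise that is
shared within a sample, which slightly inflates the recovered prior
(d₀, s₀²) relative to truth; at the study's scale (~4000 features) the
recovery is clean. Relatedly, if a large fraction of a *small* platform's
features is strongly deregulated (the 3% GC-MS split), median scaling folds
part of that shift back into the platform's null features — an inherent
property of median normalization, not of the generator.

## Numerical choices

- Trigamma inversion: Newton iteration on 1/ψ′ from y = 0.5 + 1/x,
  asymptotic branches for extreme arguments, tolerance 1e-10.
- Zero residual variances are floored at 1e-12 × the smallest positive
  variance before the log in prior estimation; all-zero variances raise.
- Zero posterior variance with zero effect yields t = 0 (p = 1); with a
  nonzero effect it raises rather than emitting ±∞.
- Rotation unit vectors are normalized standard-normal draws
  (`numpy.random.default_rng`, PCG64); fixed seed ⇒ bit-identical results.
  Rotations are processed in blocks (~5·10⁶ matrix entries) to bound
  memory at study scale.
- Intensity tables are written with 17 significant digits and read with
  round-trip float parsing, so write∘read is bit-identical.
- BH ties are resolved by stable sort; heatmap leaf order uses scipy's
  deterministic ordering on the id-sorted input.

## Problem sizes in tests

The default suite runs the generator at m = 600 (n = 6 + 6), rotation tests
at B = 199–1999, the singleton calibration at B = 10⁵ over 4 features, the
null calibration on 50 disjoint pathways (m = 900), and the power check on
3 × 10 deregulated pathways with |shift| ≥ 2 at B = 999 — about 15 s in
total.

## Known limitations

- Two-group designs only: no covariates, batch terms, paired samples, or
  robust/trended prior variants.
- The per-metabolite BH m depends on the annotation supplied; published
  adjusted p-values are reproducible only given the original m.
- Coeluting features are excluded from pathway analysis entirely rather
  than fractionally assigned.
- The rotation p floor is 1/(B+1); very small pathway p-values require
  large B (config knob) or remain at the floor.
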