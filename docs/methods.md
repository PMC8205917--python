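# Methods

This note documents the statistical procedures implemented in `mirpanel`,
the synthetic data model used to exercise them, the numerical choices, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Normalization and filtering

Serum microarray profiles carry a per-sample multiplicative technical
factor (serum input, labeling, hybridization). `normalize_to_controls`
divides every signal of a sample by the mean of three designated internal
control miRNAs and multiplies by a *reference level* — the grand mean of
per-sample control means, estimated once on the discovery arm and frozen
into the model file. Dividing by the control mean cancels any sample-wide
factor exactly; the frozen reference keeps values on the familiar raw
fluorescence scale (so the conventional robustness threshold of 64 units
stays meaningful) and prevents information flowing backwards from
validation or future cohorts. The operation is idempotent under a frozen
reference.

Control suitability is assessed with the geNorm-style pairwise-variation
statistic: M of a control is the mean, over the other controls, of the
standard deviation (n − 1 denominator) across samples of the pairwise
log2 ratio. M is invariant to sample-wide factors and is therefore
exactly the co-stability assumption normalization relies on. The pipeline
warns when any M exceeds 1.0, a customary rule of thumb.

The robust filter keeps a miRNA iff its normalized signal strictly
exceeds the threshold (default 64) in strictly more than a fraction
(default 0.5) of samples, *in each group* by default ("each" is the
literal reading of the inclusion rule; an `any_group` variant is
available). Both inequalities are strict, so a miRNA sitting exactly at
64, or above it in exactly half a group, is excluded. Internal-control
miRNAs are never candidates.

Discriminant features are log2 of the normalized signal, floored at 1
(log-intensity is the standard scale for fluorescence data; the floor
keeps features non-negative and finite at the detection floor). The scale
tag travels with matrices and models, so a model cannot silently be
applied to data on the wrong scale.

## Discriminant, search, and selection

`fit_fisher_lda` computes w = S⁻¹(μ_case − μ_control) with the pooled
within-class covariance on n − 2 degrees of freedom and the midpoint
intercept −wᵀ(μ_case + μ_control)/2. A singular S falls back to a ridge
(ε·trace(S)/p on the diagonal, ε = 1e−8 — small enough not to perturb
well-conditioned fits, verified by test) with a logged warning.

LOOCV refits the discriminant for each held-out sample and classifies it
at the midpoint cutoff 0. The hot path expresses each leave-one-out fit
as a rank-one downdate of the held-out sample's class mean and scatter
and solves all n linear systems in one stacked call; the test suite pins
it against an explicit per-sample refit loop to ~1e−8 on random
instances. On null data LOOCV is *pessimistically* biased for this
classifier family (removing a sample shifts its own class mean away from
it), so chance-level features can score well below 0.5 accuracy;
the tests assert this direction of bias rather than a symmetric band.

The greedy search is strictly forward, no swaps or backtracking: size k
adds the candidate maximizing LOOCV accuracy of the union, ties broken by
higher in-sample AUC, then lexicographic miRNA id — fully deterministic.
Youden recentring is applied only to the final model, not per LOOCV fold
(cheaper, and the operating cutoff is a property of the finished index):
the threshold maximizing J = sensitivity + specificity − 1 is sought over
the observed training scores with "score ≥ t is positive"; among ties the
smallest t wins (maximizing sensitivity, the natural choice for a
screening test), and the intercept is shifted so that threshold is
exactly 0. A sample exactly at the cutoff is classified positive, again
favoring sensitivity.

Model size is selected from the nested DeLong comparisons: the largest k
whose AUC significantly beats k − 1 (two-sided paired DeLong p < α,
default 0.05) while k + 1 adds nothing significant; if no size qualifies,
k = 1. Pearson χ² p-values on LOOCV accuracy are reported alongside in
the combinations table but do not drive selection. No multiplicity
correction is applied anywhere; nested p-values are reported raw.

## ROC and confusion inference

AUC uses the midrank (Mann–Whitney) estimator; its variance and the
paired test come from the DeLong structural components V10/V01, so ties
contribute ½ exactly and the trapezoidal area under the emitted ROC
polyline equals the AUC to machine precision. The paired z-statistic uses
var(A) + var(B) − 2 cov(A, B) from paired components; a zero-variance
difference (identical or rank-equivalent scores) returns p = 1 when the
AUCs agree. Sensitivity/specificity/accuracy intervals are Wald,
p ± 1.96·√(p(1−p)/n), clipped to [0, 1] — this reproduces printed
intervals of the form 0.983 (0.974–0.993) at n = 708. PPV/NPV are Bayes
point estimates at a configured prevalence (default 0.00742); no
intervals are attached to them. Covariate balance uses pooled-variance
t-tests for age and Pearson χ² (no continuity correction) for categorical
covariates, with the placeholder level `none` excluded where it marks
non-applicability.

## Synthetic cohorts

The generator emulates a matched case–control serum microarray study.
Per miRNA m and sample s,

    log2 x = baseline_m + effect_m·1[case] + loading_m·Z_s
             + batch(source_s) + tech_s + N(0, sd_m),
    x_raw  = max(2^log2 x, floor)

with Z_s ~ N(0,1) a shared latent nuisance, tech_s ~ N(0, 0.3²) the
sample-wide technical factor, and additive log2 offsets (0, 0.15, −0.15)
per control serum source; batch and technical terms act uniformly on all
miRNAs of a sample, so internal-control normalization removes them
exactly (tested to machine precision). Signals are log-normal with a hard
detection floor at 8 units — far below the filter threshold of 64, so
filtering is exercised rather than saturated. Because serum is miRNA-poor,
null baselines are a two-component mixture: a fraction 0.18 of species is
expressed (baseline log2 uniform on [7, 13]) and the rest sit near the
floor (uniform on [3, 6]); with the default 300 miRNAs this yields roughly
40–70 filter-passing candidates, matching the ~16% pass-rate typical of
serum chips. The three internal controls have zero group effect and
loading, sd 0.05, and baselines around 2^10.

Default planted markers (effects in log2 units, noise sd 1): up +3.0 with
latent loading 1, down −1.5, moderate +1.0, and a *suppressor* with zero
group effect but loading 1 shared with the up-marker. Their closed-form
marginal AUCs, Φ(effect / (σ_tot·√2)) with σ_tot² = sd² + loading², are
approximately 0.93, 0.86, 0.76 and 0.50 — spanning the range a real panel's
members exhibit. The suppressor construct is the chosen mechanism for the
observed phenomenon of a near-chance miRNA that still raises a panel's
AUC: a discriminant including it can subtract the latent noise it shares
with a true marker. A weakened variant (`recovery_markers`: +1.6/−1.2/+0.8
plus the suppressor) is provided for stress-testing the search.

Covariates mimic the motivating study's discovery arm: control sources
0.351/0.327/0.322, case stages IA/IB/II at 0.952/0.041/0.007, histology
0.564/0.422/0.014, age ~N(65, 11²) clipped to [20, 90], 72% male.
Compositions follow these proportions exactly (largest-remainder
rounding, then shuffled); matching is emulated by drawing both groups
from identical covariate distributions, and covariates do not enter the
signal model. The discovery/validation split is stratified by group and,
within controls, by serum source; when a group's quota is fractional the
case group rounds down and the control group rounds up, so equal odd-sized
groups split complementarily (1417 + 1417 at 1:1 → 708/709 and 709/708).

Default cohort size is 200 + 200 samples and 300 miRNAs: large enough for
the asymptotics the inference relies on, small enough that a full
discovery run takes about a second, and the size used throughout the
tests and the acceptance script. What passing tests on these cohorts do
*not* show: behavior under real-world batch structure that is not
sample-wide (probe-specific batch effects), non-log-normal signal
distributions, covariate-linked expression, or cohorts where controls are
not source-stratifiable.

## Unsupervised summaries

Clustering of samples on the selected panel uses distance 1 − Pearson
correlation between per-miRNA-standardized feature vectors with Ward
linkage, cut at two clusters; agreement with the true labels is the best
matching fraction over cluster relabelings. PCA standardizes each panel
miRNA (mean 0, sd 1) and eigendecomposes the resulting correlation
structure; explained-variance fractions are reported over all components
(they sum to 1) and sample coordinates for the first three, each
determined up to sign. Zero-variance miRNAs are dropped with a warning.

## Known limitations

* Greedy forward search under LOOCV accuracy is noisy when many null
  candidates survive filtering: a marker whose accuracy contribution is
  within ~2 percentage points of the max-over-candidates selection noise
  (at 400 discovery samples, roughly effects below ~1 log2 unit) is
  recovered in only a fraction of runs. With the default marker strengths
  the size-4 panel contains at least three of the four planted markers in
  roughly 80–85% of cohorts; with the weakened `recovery_markers` set the
  rate drops to roughly 60%. This is a property of the selection
  criterion, not of the implementation (which matches the brute-force
  LOOCV oracle exactly).
* DeLong inference is asymptotic normal; no exact or permutation variant
  is provided.
* PPV/NPV are point estimates; no interval method is implemented.
* No background correction, quantile normalization, or batch-correction
  method; the internal-control rescaling is the only normalization.
* The model JSON records the feature scale and normalization provenance
  but cannot detect a semantically wrong (yet same-scale) input matrix.
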