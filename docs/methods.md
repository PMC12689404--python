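# Methods

## Study design being modelled

The discovery arm is a mouse serum miRNA experiment in a 2×2 factorial
design: treatment (saline Control vs MPTP, a neurotoxin producing
selective dopaminergic injury) crossed with sampling day (D0, immediately
after dosing; D5, five days later), with 4 biological replicates per
cell and ~3,163 array probes on a log2-intensity scale. The scientific
contrast of interest is the D5−D0 change *within* the MPTP arm: temporal
change specific to the treated animals. The validation arm applies a
panel derived from the mouse data to human PD/Control cohorts measured
on two platform families — continuous array-like log intensities (PBMC)
and small-RNA sequencing counts from serum exosomes.

## Differential expression with moderated variances

Each feature is fitted with the saturated cell-means parameterization of
the 2×2 design (equivalent to group + time + group:time dummy coding; the
within-group time effect is then simply a difference of two cell means).
The residual variance s²_g pools within-cell scatter with d = N − 4
degrees of freedom (d = 12 at the default design).

Variances are moderated with the standard empirical-Bayes hierarchy for
gene-wise variances: s²_g | σ²_g ~ σ²_g χ²_d/d and
1/σ²_g ~ χ²_{d₀}/(d₀ s₀²), giving the posterior

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d).

The hyperparameters are estimated by the method of moments on
e_g = log s²_g − ψ(d/2) + log(d/2):
ψ′(d₀/2) = var(e) − ψ′(d/2) is solved for d₀ by Newton iteration on the
(monotone) trigamma function, and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When var(e) does not exceed
ψ′(d/2) — i.e. the observed spread of log-variances is no larger than
pure χ² sampling noise — the prior is degenerate: d₀ = ∞ and every
posterior variance equals exp(mean(e)). This branch is the norm for the
synthetic generator, whose features share a single true noise variance.
Features with s²_g = 0 are excluded from hyperparameter estimation but
still moderated; a data set in which *every* variance is zero raises.

The moderated t for the contrast uses s̃_g and d₀ + d degrees of freedom
(standard normal when d₀ = ∞). Multiplicity is controlled with the
Benjamini–Hochberg step-up procedure; significance defaults to FDR < 0.05.

## Global permutation test

Feature-level tests at n = 4 per cell are individually weak, so a
dataset-level statistic asks whether temporal signal is concentrated in
the treated arm: per feature, two-sample pooled-variance t statistics of
D5 vs D0 within MPTP and within Control, combined as
T = Σ t²_MPTP − Σ t²_Control. An MPTP-only variant (Σ t²_MPTP) is
available; the difference form is the default because it nets out
handling/time effects common to both arms. Ordinary (unmoderated) t is
used inside the statistic — moderation is a concern of the per-feature
analysis, and permutation calibration does not need it.

The null permutes day labels independently within each treatment group;
group membership never changes. With 4+4 animals per group there are only
C(8,4)² = 4,900 distinct joint assignments, so both modes are provided:
exhaustive enumeration (exact p, observed assignment included, so p > 0)
and Monte-Carlo sampling with replacement among assignments, using the
add-one estimator p = (1 + #{T* ≥ T_obs})/(B + 1). Sampling with B larger
than the number of distinct assignments is allowed (it matches the
conventional choice B = 5,000) but triggers a pointer to exhaustive mode.

A property of this scheme worth knowing: when strong effects are planted
at D5, within-group permutations that overlap the true day split retain
part of the signal (and the complement retains all of it, since t² is
sign-blind). The permutation distribution therefore has a heavy right
tail under strong alternatives, and one-sided p-values for genuinely
strong signal settle in the 0.05–0.25 range at the default effect sizes
rather than collapsing to the floor. The test is calibrated under the
null — type-I error at α = 0.05 is verified to lie in [0.03, 0.08] over
200 null simulations — but its power against dense alternatives is
intrinsically modest at this sample size.

## Day-0 classifier and stability selection

Classifier development uses day-0 samples only (4 MPTP vs 4 Control):
can treated animals be recognized before the day-5 response unfolds?

* **Univariate filter.** Top-k features by absolute two-sample
  pooled-variance t, k = 20; ties break lexicographically by feature ID
  so results are deterministic. Zero-variance features get t = 0.
* **LOOCV.** For each held-out sample, the filter is recomputed on the
  remaining 7, features are standardized on the training split, and an
  elastic-net logistic model is fitted for each α ∈ {0.1, 0.5, 0.9} with
  λ chosen by stratified internal cross-validation (held-out deviance
  over a 10-point grid anchored at λ_max, the smallest λ that zeroes all
  coefficients). Performance is the *pooled* AUC over all held-out
  decision values — a per-fold AUC is undefined for singleton folds.
* **Stability selection.** 2,000 iterations; each draws 2 samples per
  class without replacement (only C(4,2)² = 36 distinct subsamples
  exist, so the iteration average converges to the exact equal-weight
  enumeration — verified in the tests), re-runs the filter on the
  subsample, standardizes, and fits one elastic-net logistic model at
  fixed α = 0.5 and λ = 0.1·λ_max of that subsample. Internal CV is
  impossible at n = 4, hence the fixed-fraction rule; both the fraction
  and α are configurable. π̂ is the fraction of (non-degenerate)
  iterations in which a feature's coefficient is exactly nonzero —
  the solver's soft-thresholding makes zeros exact, so no tolerance
  cutoff is involved. Features with π̂ ≥ 0.6 form the panel, with the
  direction of each member taken from the sign of its D5−D0 log2 fold
  change in the treated arm.
* **Selection-frequency null.** Class labels are permuted B times and the
  whole stability pipeline re-run (with a reduced per-permutation
  iteration count, default 200, since 2,000 × 2,000 full-fidelity fits
  serve no inferential purpose); the null statistic is the number of
  features reaching the threshold (alternatively the mean π̂ of the top-m
  features), and p uses the add-one estimator.

The penalized logistic fits use an in-package batched FISTA solver with
exact soft-thresholding (glmnet parameterization: mean log-loss plus
λ(α‖β‖₁ + (1−α)/2‖β‖₂²), unpenalized intercept, columns standardized to
population SD 1). The solver is verified against an independent
coordinate-wise implementation (scikit-learn's saga) in the test suite;
batching matters because stability selection and its permutation null
run ~10⁵ four-sample fits.

### A hard limit of the top-k filter at full feature count

With 2+2 subsamples the filter's null t statistic has 2 degrees of
freedom; a t₂ distribution has such heavy tails that the 20th-largest
absolute value among ~3,000 null features is ≈ 12–13, while a planted
3-SD group separation yields a noncentral t₂ (ncp 3) that exceeds that
bar in only ~6% of subsamples. Consequently, at the full default feature
count (3,163) planted panel members cannot accumulate π̂ ≥ 0.6 no matter
how the downstream elastic net behaves, and the day-0 panel is typically
empty; at the same effect sizes with ≤ ~100 background features the
procedure recovers the planted panel reliably (π̂ 0.6–1.0, background
typically below 0.3). The package implements the procedure as specified
and documents this regime boundary rather than altering the filter; unit
tests exercise recovery in the feasible regime, and the acceptance suite
records the infeasibility at full scale honestly. The mirror image of
the same phenomenon: with a small background and a fixed 8-sample data
set, one lucky noise feature can dominate every subsample, so the
"no false selections under the null" property conversely requires a
*large* background. Both behaviors are consequences of reusing the same
8 animals across all subsamples, not of the solver.

## Cross-species harmonization

Names are reduced to a canonical core: species prefix mmu→hsa,
lowercase, trailing `-5p`/`-3p` arm suffixes stripped (repeatedly, making
the map idempotent); e.g. `mmu-miR-92b-3p` → `hsa-mir-92b`. The
serialization (prefix retained, lowercase `mir`) is this package's
convention. Identifiers from other species (viral miRNAs in older array
annotations) are flagged for exclusion rather than silently mapped.
Probes sharing a core name are collapsed by the arithmetic mean on the
stored (log) scale. Sequence comparability is judged on the seed region,
defined here as nucleotides 2–8 (1-based, 7 nt) of the mature sequence.
For the six-member signature, five mouse/human pairs are identical at
full length; miR-326 differs because the mouse panel carries the 5p arm
while human annotation features the 3p product of the same precursor —
it is retained, flagged, on the grounds of shared locus and regulation.

## Signature scoring and validation

Count matrices are brought to log2(CPM + 1) with per-sample library
sizes; log-intensity matrices pass through unchanged. Each feature is
z-scored across samples (n−1 denominator; constant features become zero
with a warning). The composite score is

    S_i = mean_{g ∈ down}(−z_{gi}) − mean_{g ∈ up}(z_{gi}),

so loss of down-regulated members raises the score; panel members are
matched on core names after normalization, multiple matches averaged, and
missing members reported as a coverage fraction.

AUC uses the rank (Mann–Whitney) formulation with ties counted ½ and PD
as the positive class. Because real cohorts differ in which direction
separates cases, the headline AUC is orientation-free — max(A, 1−A) with
the orientation recorded — and the permutation null recomputes exactly
the same max-folded statistic, which keeps the p-value valid (the naive
one-sided null would be anti-conservative under folding; calibration is
verified by simulation in the tests). The 95% CI is a stratified
percentile bootstrap (resampling within class, 2,000 resamples) of the
AUC in the orientation fixed by the observed data. The operating point
maximizes Youden's J over observed cut-points, ties broken toward higher
sensitivity. The permutation p defaults to the add-one estimator; the
literal proportion #{A* ≥ A_obs}/B is available by flag.

## Synthetic data generator

The generator emulates structure, not biology:

* **Mouse arm** — per-feature baselines Uniform(4, 12) log2 units,
  i.i.d. Gaussian noise (SD 0.5); 15 features planted with a −2.0 log2FC
  and 2 with +1.4 at MPTP×D5 (magnitudes mirroring the discovery study's
  printed extremes); the six signature features additionally separated
  between groups by 1.5 log2 units at both days, so a day-0 classifier
  has signal. Feature IDs reuse the real panel's mouse names so the
  harmonization path is exercised end to end.
* **Human cohorts** — array platform: Gaussian features with a
  standardized PD shift (default 0.8 SD, direction per panel member) on
  panel features; count platform: negative-binomial counts (dispersion
  0.3, library sizes uniform in 2×10⁵–10⁶) with the equivalent log2 fold
  change computed by the delta method (σ_log2 ≈ √(1/μ + φ)/ln 2). Column
  headers follow either the PD/Control-prefix dialect or the positional
  dialect (S001–S050 PD, S051–S100 Control; this dialect therefore
  requires a 50+50 cohort).
* Background features are exchangeable noise with no correlation
  structure, no batch effects, and no probe-level artifacts. Passing
  tests on these data demonstrate the statistical machinery is correct
  and calibrated — not that the signature works on real cohorts, where
  correlated features, platform batch effects and confounders (age,
  medication) exist.

Every generator is a pure function of its spec including the seed;
identical specs are byte-identical. The distributional families are this
package's choices — the platforms' true generative processes are not
modelled.

## Determinism and problem sizes

All pipeline randomness derives from one master seed (default 20,250,912)
through named CRC-tagged substreams, so stages are reproducible in
isolation and reruns are byte-identical. Paper-scale defaults are
B = 5,000 (global test and AUC permutations), B = 2,000 (selection
permutations), 2,000 stability iterations; a desk-scale profile
(500/300/100/500) is provided for interactive runs and CI. Simulation
based tests use deliberately scaled problem sizes chosen to make their
Monte-Carlo error small relative to the asserted margins: 200 null
datasets at 300 features for type-I calibration of the global test
(calibration does not depend on feature count), 3,000 features for
hyperparameter recovery, 50 generator seeds for recovery/validation
fractions.

## Known limitations

* The global test's power against dense, strong alternatives is limited
  by within-group permutation overlap (see above).
* The day-0 top-20 |t| filter cannot surface 3-SD effects from a
  3,163-feature background at n = 2+2 (see above); panel recovery at
  full feature count would require either larger subsamples, a
  variance-stabilized filter statistic, or stronger day-0 separation.
* LOOCV at n = 8 with thousands of candidate features is dominated by
  filter noise for the same reason; pooled AUC on full-size synthetic
  data is uninformative (and often inverted), while in the ≤100-feature
  regime it exceeds 0.9.
* The count-platform preprocessing (log2-CPM + 1 before z-scoring) is a
  pragmatic default; no attempt is made to model compositional effects.
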