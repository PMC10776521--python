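# Methods

## The problem

Pooled multi-site MRI collections make it possible to train classifiers that
separate subjects with autism spectrum disorder (ASD) from typically
developing controls (TD), but they bring two structural difficulties: the
diagnostic signal is weak and distributed across modalities, and each
acquisition site imprints its own location/scale signature ("batch effect")
on every derived feature.  This package implements the full analysis chain
for that setting — feature construction from regional timeseries and
morphometric tables, control-anchored harmonization, a joint-fusion neural
classifier evaluated under nested cross-validation, and cross-modality
Shapley attribution — and validates every stage against a synthetic cohort
generator with known planted structure.

## Synthetic cohort generator

The generator emulates the statistical shape of a male, 5–40-year,
35-site ASD/TD sample without touching any real data:

* **Sites and ages.** A site plan fixes (n_ASD, n_TD) per site; the packaged
  full-scale plan has 35 sites and 1383 subjects (680 ASD / 703 TD).  Ages are
  truncated-normal, mean 15 y, SD 7 y on [5, 40], matching the pooled
  sample's reported moments.  The package's *desk scale* — used by the
  analysis drivers, the tests and the acceptance script — is 10 sites × (30
  ASD + 30 TD), 50 atlas regions, T = 150 timepoints; this keeps a full
  pipeline run in minutes while preserving the multi-site geometry.
* **Functional data.** Per-subject regional timeseries are zero-mean
  multivariate normal draws.  The base correlation matrix is block
  structured (five blocks, within-block ρ = 0.3), eigenvalue-clipped to
  positive definite; it is configurable because no generative model of real
  connectomes is implied.  Diagnosis effects add Δρ = ±0.3 on a sparse list
  of region pairs: negative on long-range inter-hemispheric pairs
  (hypo-connectivity in ASD), positive on short intra-hemispheric pairs
  (hyper-connectivity), the direction pattern repeatedly reported for ASD.
  Site batch effects add a small per-site offset to all off-diagonal
  correlations (SD 0.03).
* **Structural data.** The 221-name morphometric schema (9 globals, 26
  subcortical/corpus-callosum volumes, 62 DKT cortical regions × volume /
  mean thickness / thickness SD) is populated as baseline + smooth age trend
  + diagnosis effect + site location + site-scaled noise.  Diagnosis effects
  are Cohen's d = ±0.8 on a few thickness/volume features; site effects are
  drawn once per cohort (location SD 0.8, log-scale SD 0.15) and stored in
  the cohort's truth object so tests can check recovery.  The age trend is a
  cubic polynomial in (age − 15)/10.
* **What it does not emulate.** Raw images, spatially correlated
  morphometric noise, site-by-age interactions, heterogeneous timeseries
  lengths, missing-at-random phenotype fields, and the heavy-tailed motion
  artefacts of real rs-fMRI.  Passing tests therefore demonstrate that the
  *machinery* is correct and well calibrated, not that real-data performance
  is reproduced.

A deliberate property of these defaults: a Δρ = 0.3 correlation shift is an
enormous effect in Fisher-feature units (≈ 4.6 SD at T = 150), while d = 0.8
is a moderate one, so the functional modality dominates the fused model just
as it does in the real cohort.

## Functional connectivity features

Pearson correlation between every pair of regional timeseries; Fisher
transform arctanh(r); scaling by √(T−3) so features have unit SD under the
null (verified by simulation: SD within [0.97, 1.03] at T = 150); |r| is
clipped at 1 − 10⁻⁶ so perfect correlations stay finite.  The upper triangle
(row-major, i < j) is vectorized with names `fc__<regionA>__<regionB>`; R
retained regions give R(R−1)/2 features (103 → 5253).  Regions missing in
more than a fraction (default 0.1) of subjects are dropped cohort-wide
rather than dropping subjects; a retained region sporadically absent in one
subject contributes the null feature value 0 for its pairs.  Each subject
uses its own T in the scaling, so cohorts with heterogeneous scan lengths
remain calibrated.

## Harmonization

Per feature v: y = α_v + f_v(age) + γ_iv + δ_iv ε, fitted on controls only
(the API refuses tables with case labels unless overridden), then applied to
everyone — diagnosis never enters the adjustment.  f_v is a natural cubic
spline (df = 5, knots at control-age quantiles; df configurable) estimated
jointly with full site dummies by least squares; α_v is the site-size-
weighted grand mean; σ_v² the pooled residual variance.  Per-site location
and scale of the standardized residuals are shrunk by parametric empirical
Bayes (normal prior on γ across features, inverse-gamma on δ², moment
matched, iterated to convergence); a non-EB mode exists for debugging small
cohorts.  Adjustment: y* = σ_v (z − γ*_iv)/δ*_iv + α_v + f_v(age).

γ is identified relative to the grand mean, so recovery of a planted offset
is assessed as the contrast of the shifted site against the mean of the
unshifted sites.  Effect-size preservation is judged against a *twin* cohort
generated with identical subject-level noise but site effects switched off;
the harmonized Cohen's d matches the twin's to under 1% in the packaged
check, while a site-identification classifier drops from well above to at or
below chance.  Harmonization is fit once on the full control cohort before
cross-validation, mirroring the reference protocol; we note this leaks
marginal feature statistics across CV folds and is therefore mildly
optimistic — a per-fold refit is possible through the same API for
sensitivity analyses.  Structural and functional tables are harmonized
independently.

## Classifier

Each modality block passes through its own feature-reduction network
(FR-NN): two Dense + BatchNorm + ReLU layers, widths 64→32 (structural) and
256→128 (functional), embeddings proportionate to the input widths.  The
embeddings are concatenated and classified by a head (C-NN) whose
depth ∈ {1, 2} and width ∈ {32, 64, 128} are selected in the inner CV loop;
dropout 0.5 after the first head layer and 0.2 after the second; a single
logistic output.  Training: SGD with momentum 0.9, learning rate 0.001,
batch 64, binary cross-entropy, 150 epochs at full scale, and L1 (0.01) on
each FR-NN's first weight matrix, which acts as input feature selection.
The loss backpropagates through the FR-NNs (joint fusion); a `freeze_frnn`
ablation disables their updates and measurably degrades held-out AUC on
complementary-signal data.  The network is implemented directly in NumPy
with hand-written backpropagation; the same backward pass supplies input
gradients for attribution.  Training is deterministic given the seed.

Features are scaled by training-split median/IQR (linear-interpolation
quantiles; zero-IQR features are centred, not scaled).  Evaluation is nested
stratified 10-fold CV (folds stratified by diagnosis only); the scaler and
the inner selection see only training rows, enforced by an audit log of
subject-id usage that tests assert over.  At desk scale (n = 600) fewer
outer folds keep each training split large and each test fold stable: the
analysis drivers use 5 outer folds with a 2-point head grid, and the
modality-comparison experiment uses 3 outer folds with a fixed head.  The
full 150-epoch schedule is kept even at desk scale — the weak connectivity
signal is severely underfit at 30–60 epochs, and every modality's AUC rises
substantially between 60 and 150 epochs.

## Metrics and comparison

AUC is the trapezoidal area under the empirical ROC (equal to Mann–Whitney
concordance with ties at ½ — asserted against an O(n²) brute force to
1e−12).  Fold curves are averaged vertically on a fixed FPR grid (0, 0.01,
…, 1); summary AUC mean ± SD always comes from per-fold AUCs (sample SD,
n−1).  Two models sharing outer folds are compared by a paired permutation
test: per-subject score swaps between models, statistic = pooled AUC
difference, one-sided p with the +1 correction.  The test is assumption-free
and its null p-distribution is checked for uniformity.

## Attribution

Shapley values are approximated by expected gradients:
Φ_i = E_{b,α}[(x_i − b_i) ∂F/∂x_i(b + α(x − b))] with baselines b from a
background sample and α ∈ (0, 1).  The estimator enumerates every background
baseline and stratifies α into m = n_samples/n_bg jittered strata per
baseline — unbiased, with far lower variance than iid sampling; the
completeness identity ΣΦ ≈ F(x) − E_b F(b) holds to a few percent at 500
samples on a trained network and exactly (to sampling error < 1%) on a
linear model.

Per-feature importance is S = mean |Φ| over instances.  Because the two
modalities differ in dimensionality, scores are normalized within modality
and weighted by modality size: S_norm = S/Σ_m S · N_m/(2(N_s + N_f)), so the
grand total is exactly ½ and per-feature means are equal across modalities.
The reference protocol repeats attribution over many resampled inner-CV
training splits and averages; we implement exactly that
(`repeated_split_importance`): each repetition draws a stratified 90/10
split, retrains the fusion model, draws a fresh 100-subject background, and
attributes all subjects.  At desk scale the package default is 20
repetitions of 60-epoch models: averaging over independently trained models
is what stabilizes the ranking of weakly used features — single-model
attributions recover markedly fewer planted features — and shorter training
per ensemble member suits the smaller cohort.  Features strictly above the
99th percentile of S_norm are reported with a signed Cohen's d, pooled as
the group-size-weighted average of the two group SDs, matching the
convention of the effect-direction table this mirrors.

## Numerical and design choices

* Quantiles everywhere use linear interpolation (NumPy default).
* Fisher clip at |r| = 1 − 10⁻⁶; positive-definiteness restored by
  eigenvalue clipping at 10⁻⁴ and re-normalization to unit diagonal;
  a diagnosis-conditional shift that breaks positive definiteness raises an
  error naming the offending pairs.
* Percentile selection is strict (">"), so exact ties at the threshold are
  excluded; at the threshold "percentile 0" this excludes minimum ties.
* Inner-CV ties in mean AUC resolve to the first candidate in the declared
  search grid.
* Accuracy thresholds the logistic output at 0.5 (score > 0.5 → ASD).
* All randomness flows from integer seeds through `numpy.random.SeedSequence`
  spawning; identical configuration and seed reproduce cohorts, fold
  assignments, training and attribution bit-for-bit.

## Known limitations

* Cohort-level harmonization before CV is mildly optimistic (see above).
* Real-cohort headline AUCs are not reproduced here by design;
  synthetic-scale AUCs depend on the planted effect sizes.
* Expected gradients assume a differentiable model; the ReLU network is
  differentiable almost everywhere, which is sufficient in practice but the
  path integral is approximated, not exact.
* The EB priors are the standard parametric ones; sites with very few
  controls (< 3) are rejected rather than modelled.
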