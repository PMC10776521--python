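# neurofuse

Joint-fusion classification of multi-site structural and functional brain
MRI features, with control-anchored site harmonization and Shapley-based
explainability — exercised end to end on a synthetic multi-site cohort
generator with known planted ground truth.

## Who this is for

Researchers building ASD-vs-TD (or any case–control) classifiers on pooled
multi-site MRI collections, where three problems interact: per-site batch
effects confound every feature, the diagnostic signal is split across
modalities, and deep models need a defensible account of *which* features
drive their decisions.  The package provides the full analysis chain as a
tested library plus numbered analysis drivers, and a cohort simulator so
every stage can be validated against planted truth without downloading any
data.

## The model

**Features.** Structural: a 221-feature morphometric vector (9 globals, 26
subcortical/callosal volumes, and volume, mean thickness and thickness SD
for the 62 DKT cortical regions), parseable from Freesurfer
`aseg.stats`/`aparc.stats` text files.  Functional: pairwise Pearson
correlations r between regional timeseries, Fisher-transformed and scaled,
z = arctanh(r)·√(T−3), vectorized over the non-redundant upper triangle —
R(R−1)/2 features (103 retained regions → 5253).

**Harmonization.** Per feature v, y = α_v + f_v(age) + γ_iv + δ_iv·ε with
site location γ and scale δ, a natural-spline age trend f_v, fit on controls
only and applied to everyone; γ, δ are shrunk by parametric empirical Bayes
(ComBat lineage).

**Classifier.** One feature-reduction network (FR-NN) per modality maps its
block to a fixed-length embedding; the concatenated embeddings feed a
classification head (C-NN) with a single logistic unit.  The loss
backpropagates through the FR-NNs (*joint fusion*).  SGD (lr 0.001, momentum
0.9), BCE, batch normalization, dropout (0.5, 0.2), L1 = 0.01 on each
FR-NN's first layer.  Evaluation: nested stratified 10-fold CV; the inner
loop selects the C-NN depth/width; AUC and accuracy are reported as
mean ± SD over outer folds.

**Explainability.** Expected-gradients Shapley values Φ; per-feature
importance S = mean|Φ|; cross-modality normalization
S_norm = S/Σ_m S · N_m/(2(N_s+N_f)) (grand total exactly ½); features above
the 99th percentile are reported with a signed Cohen's d,
(μ_ASD−μ_TD)/SD_pooled.

The neural network and the attribution estimator are implemented directly in
NumPy with hand-written backpropagation; everything is deterministic given a
seed.

## Worked example

The numbered drivers under `analysis/` run the desk-scale study (10 sites ×
30 ASD + 30 TD, 50 regions, T = 150, seed 1) and write everything under
`results/run/`:

```bash
python analysis/01_simulate.py
python analysis/02_build_features.py
python analysis/03_harmonize.py
python analysis/04_train_models.py
python analysis/05_explain.py
```

Output of the run at seed 1 (abridged):

```
cohort: 600 subjects, 10 sites
ASD    300
TD     300
age range 5.2-37.3 y, mean 16.2
feature table: 600 subjects x 1446 features
  structural 221, functional 1225
site-identification accuracy: 0.565 before -> 0.010 after (chance 0.100)
structural: AUC 0.593 +- 0.037, accuracy 0.562 +- 0.038
functional: AUC 0.782 +- 0.047, accuracy 0.705 +- 0.029
     joint: AUC 0.778 +- 0.032, accuracy 0.705 +- 0.041
joint vs functional: dAUC -0.007, one-sided p = 0.585 (1000 permutations)
features above the 99th percentile: 15
planted informative features recovered: 8/8
```

Reading this: harmonization erases the site signature (a site classifier
falls from 0.565 to chance) without touching the planted diagnosis effects;
the functional and joint models detect the planted signal strongly while the
structural model, whose planted effects are much weaker, sits above chance;
and the attribution stage places all 8 planted informative features (3
structural effects, 5 connectivity-pair effects) above the 99th-percentile
importance cut among 1446 candidates, each with the planted sign of
Cohen's d.  At this single seed the joint-vs-functional gap is within fold
noise (p = 0.585); the aggregate joint ≥ best-single ordering over ten
cohorts — on complementary-signal effects where both modalities carry
comparable information — is checked in the test suite.

The same pipeline is scriptable through the `neurofuse` CLI
(`simulate`, `features`, `harmonize`, `train`, `explain`, `report`,
`verify`) with `--config/--seed/--out/--mode/--skip-harmonization`; `verify`
re-checks the SHA-256 manifest of a finished run.

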