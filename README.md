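# episcore

Age- and sex-adjusted DNA methylation outlier detection and episignature
classification.

## The problem

Methylation beta values (the fraction of methylated signal at a CpG probe,
in (0, 1)) drift with age and differ by sex at many loci. Clinical outlier
screens that compare a patient's probe values against a single cohort-wide
reference range therefore miss true aberrations in patients whose
demographics sit far from the cohort average — an infant's normally
low-methylated probe can look "normal" against a range dominated by adults.
episcore is for groups building methylation-based screens for imprinting and
repeat-expansion disorders (Prader–Willi, Angelman, Beckwith–Wiedemann,
Silver–Russell, Fragile X) who want demographics-aware reference ranges, a
principled way to size their control cohort, and a classifier over the
resulting z-scores.

## The model

All beta values are logit transformed, x = log(β / (1 − β)). For each probe,
a Gaussian location–scale model is fitted to healthy controls:

    x ~ N(μ(age, sex), σ(age, sex))
    μ       = s_μ(t)  + b_μ · 1[sex = M],   t = log(1 + age_years)
    log σ   = s_σ(t)  + b_σ · 1[sex = M]

with s_μ, s_σ penalized cubic B-splines (second-order difference penalty;
GCV-selected smoothing for μ), fitted by alternating penalized weighted
least squares and Fisher scoring. The fit is discretized onto a fixed age ×
sex grid (daily through the first year, monthly to 24 months, yearly to 85)
and samples are scored against the nearest grid entry. Three z-scores are
computed per probe × sample:

* **unadjusted** z = (x − globalMu) / globalSigma, against the cohort-global
  mean/SD of the control logit values;
* **adjusted** z = (x − μ) / σ, against the age/sex-specific reference;
* **regularized** z = (x − μ_λ) / σ_λ with μ_λ = λμ + (1−λ)·globalMu (same
  for σ, default λ = 0.5), shrinking the reference toward the global range to
  control false positives at modest cohort sizes.

A simulation module quantifies the type-I error and power of the three
variants over cohort size, and a classification pipeline feeds adjusted
z-scores of disease-locus probes plus UMAP global features into a bagged,
greedily weighted ensemble (gradient-boosted trees, random forest, k-NN,
multinomial logistic), evaluated with an exact binomial CI on accuracy.

A synthetic-cohort generator (logit-normal probes with age trends, sex
offsets, regional hyper/hypo effects and a diffuse SRS-like signature)
provides study-scale data for all of the above.

## Worked example

```bash
python examples/02_power_analysis.py
```

prints (500 iterations per cohort size):

```
     method  cohort_size  type1_error  power  iterations
 unadjusted           25        0.070  0.804         500
 unadjusted           50        0.054  0.752         500
 unadjusted          100        0.058  0.762         500
   adjusted           25        0.156  0.980         500
   adjusted           50        0.104  0.980         500
   adjusted          100        0.056  0.978         500
regularized           25        0.050  0.884         500
regularized           50        0.032  0.852         500
regularized          100        0.030  0.852         500
```

Each row is one detection variant at one control-cohort size: `type1_error`
is the fraction of clean synthetic points flagged at two-sided p < 0.05, and
`power` the fraction of hypermethylated points (+0.3 on the beta scale)
flagged. The unadjusted variant holds its error rate but has the least
power; the adjusted variant is the most powerful but over-calls at small
cohorts; the regularized variant keeps the error at or under the nominal 5%
while retaining most of the power gain — the trade the method is built
around.

The other examples score a BWS-like patient's disease locus before/after
adjustment (`01`), run the full classification pipeline on a synthetic
8-class cohort (`03`), and compute confusion-matrix metrics with the exact
binomial interval — e.g. 50/52 correct gives accuracy 0.9615 with 95% CI
(0.868, 0.995) (`04`).

A `episcore` console command exposes the same stages
(`simulate-cohort`, `fit-reference`, `score`, `power`, `run-all`,
`evaluate`); every subcommand takes `--seed` and `--config` and writes a run
manifest.

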