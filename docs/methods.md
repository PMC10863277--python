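# Methods

## Reference model

Beta values are clipped to [ε, 1−ε] (ε = 1e-6, configurable) at I/O and
logit transformed; the logit (M-value) scale stabilizes variance and makes a
Gaussian location–scale model reasonable. Per probe, healthy controls are
fitted with

    x_i ~ N(μ(t_i, s_i), σ(t_i, s_i)),   t = log(1 + age_years),  s ∈ {F, M}

where both μ and log σ are additive in a smooth of t and a sex indicator.
The log-age covariate concentrates flexibility in infancy, where methylation
trajectories change fastest; the reference grid mirrors that (ages in 1-day
steps from 0 to 365 days, monthly from 13 to 24 months, yearly from 3 to 85;
month = 30.4375 d, year = 365.25 d, rounded half away from zero; 461 ages
after merging the overlap between the daily and monthly ranges). Scoring
uses the grid entry nearest in days (ties to the younger age) and the exact
sex.

The smooths are P-splines: 8 cubic B-spline basis functions on uniformly
extended knots with a second-order difference penalty on the coefficients.
Uniform (unclamped) knots matter: they make the penalty's null space exactly
the linear-in-t functions, so heavy smoothing degrades to a linear age trend
rather than a distorted edge. Fitting alternates penalized weighted least
squares for μ (weights 1/σ²) with one Fisher-scoring step for the log-σ
coefficients (working response η + (r²e^{−2η} − 1)/2, constant weight 2)
until the joint Gaussian log-likelihood changes by < 1e-8 (cap 200
iterations). The μ smoothing parameter is chosen once by GCV over a small
log-spaced grid {1, 10, 10², 10³, 10⁴}; because GCV curves are nearly flat
for near-linear trends while light smoothing leaves the sparsely sampled
infancy edge badly under-determined, the heaviest λ within 1% of the GCV
minimum is taken. The σ smooth uses a fixed λ = 100 (the working response is
noisy — its conditional variance is that of a χ²₁ variable — so heavier
smoothing is appropriate); the sex term in the σ model can be disabled
(`FitSettings.sex_in_sigma`). σ is floored at 1e-4 on the grid.

Degenerate inputs: probes with fewer than 10 controls, a single sex, a
failed linear solve, or non-convergence fall back to a constant model equal
to the cohort-global mean/SD — i.e. adjusted scoring degrades gracefully to
unadjusted scoring; the fallback is recorded in the fit diagnostics. A probe
whose control values are all identical is refused (its global SD is zero and
no z-score is defined).

## Outlier scores

globalMu/globalSigma are the sample mean and SD (ddof = 1) of the control
logit values. The regularized reference is the convex combination
μ_λ = λμ + (1−λ)·globalMu, σ_λ = λσ + (1−λ)·globalSigma with λ = 0.5 by
default; λ = 1 and λ = 0 reproduce the adjusted and unadjusted scores
exactly, which fixes both boundary semantics. Because globalSigma absorbs
the age/sex spread of μ it is wider than σ for demographically dynamic
probes, so shrinkage widens the acceptance band and lowers the
false-positive rate — the mechanism behind the regularized variant's error
control at modest cohort sizes. Two-sided p-values use the standard normal
reference (the scores are plug-in standardizations, not t statistics with a
known df); the outlier call is |z| ≥ 3, inclusive.

## Synthetic cohorts

The generator draws logit-normal probe values: Normal(μ, σ) on the logit
scale with μ = μ₀ + a·log(1 + age_years) + s·1[M] and
log σ = log σ₀ + c·log(1 + age_years), inverse-logit transformed. This is
the natural generative inverse of the reference model; the distributional
family of the original per-probe fits is not recoverable, so this choice is
an explicit modeling assumption. Demographics are sex ~ Bernoulli(½) and
age ~ Uniform(0, 85) years. Random probe models span baselines μ₀ ∈ (−3, 3),
age slopes ∈ (−0.5, 0.5), sex offsets 0 with probability 0.7 (else
Uniform(−1, 1)), σ₀ ∈ (0.2, 0.8) — some probes carry demographic structure
and some do not, as on real arrays.

Disease effects add/subtract a constant on the beta scale (default 0.3,
clipped to the open unit interval) over a disease locus. The default cohort
mirrors the real disorders' patterns: BWS1 = H19 hyper + LIT1 hypo, BWS2 =
LIT1 hypo, AS2/PWS1 = opposite SNRPN aberrations, PWS2 = MAGEL2 hyper,
FXS = FMR1 hyper, and SRS1 a diffuse signature — each SRS sample perturbs
its own random 10% of all probes by ±0.15 with per-probe random direction,
emulating the heterogeneity of Silver–Russell episignatures. Region probes
use mid-range baselines (μ₀ ∈ (−1.5, 0.5), σ₀ ∈ (0.2, 0.5)) so a ±0.3
effect neither vanishes nor merely saturates the scale.

What the generator does **not** emulate: probe-probe correlation within a
locus, batch/plate effects, cell-type composition shifts, detection-p-value
artifacts, or realistic (non-uniform) age distributions. Passing tests on
these cohorts therefore demonstrate the statistical machinery under the
model's own assumptions, not performance on real arrays.

## Power simulation

Per iteration at cohort size n: draw n control demographics and values from
a fixed ground-truth probe model; fit a fresh reference model; draw one more
point as the control and add +0.3 (beta scale) to that same draw as the
hypermethylated abnormal; flag both under all three variants at two-sided
p < 0.05 (an |z| ≥ 3 rule is available). Sharing the base draw between
control and abnormal is a common-random-numbers choice: it reduces the
variance of the power-minus-type-I contrast and makes power at zero effect
equal type-I error exactly. Each cohort size gets an independent child RNG
stream from the master seed, so results are invariant to the order of sizes.

The default ground truth is μ₀ = −1.5, age slope 0.6, sex offset 0.4,
σ₀ = 0.35: a probe with strong demographic structure and a mid-low baseline.
The mid-low baseline is essential — with a high-methylation baseline the
+0.3 effect saturates at 1 for most draws and every variant flags trivially,
erasing the comparison the simulation exists to make. The original
per-probe fit this simulation was designed around is not recoverable, so
absolute power values are not comparable to any published figure; the
acceptance surface is the qualitative behavior: regularized type-I error at
or under 5% at cohort size 100, and power ordered adjusted > regularized >
unadjusted.

The desk-scale default is 2,000 iterations at cohort sizes
{10, 25, 50, 100, 200} (seconds to a minute on one CPU); the full protocol
(10,000 iterations, sizes 5–500 in steps of 5) is available through
`PowerConfig`.

A caveat worth stating: raw power of the *adjusted* variant is not monotone
in cohort size. Its plug-in (μ, σ) estimates are anti-conservative at small
n, inflating the false-positive rate (≈ 0.16 at n = 25 vs ≈ 0.06 at n = 400)
and with it raw power. What more controls buy is calibration, not raw
power — the tests assert exactly that.

## Feature engineering and classification

Stratified 80/20 split (per class: round(0.8·size) to train, remainder to
test). All selection is fitted on the training set and frozen: probes must
reach |z_adjusted| ≥ 3 in at least one training sample (both configurable);
surviving disease-locus probes contribute their adjusted z-scores as target
features (de-duplicated across regions, first-occurrence order); surviving
non-target probes are embedded by UMAP (default 50 components, 15
neighbors, min_dist 0.1, Euclidean, fixed seed; random initialization,
because spectral initialization is unreliable when the embedding dimension
approaches the sample count, and a fixed random_state makes UMAP
single-threaded and reproducible). Target and UMAP columns are concatenated
(98 + 50 = 148 under the published configuration) and pruned by the caret
`findCorrelation` heuristic: repeatedly take the most correlated remaining
pair above 0.9 and drop the member with the larger mean absolute
correlation (ties to the later column); zero-variance columns are dropped
first with a warning.

The classifier is four base learners — LightGBM gradient-boosted trees,
random forest, k-NN and multinomial logistic regression (the latter two
behind a standardizing scaler) — each bagged over stratified 5-fold splits
(k reduced with a warning if the smallest class is smaller), with
out-of-fold class probabilities collected for every training sample.
Ensemble weights come from Caruana-style greedy forward selection with
replacement (25 rounds) on the out-of-fold probabilities; the best-scoring
greedy prefix is kept, so the ensemble's out-of-fold accuracy never falls
below the best single learner's. Prediction averages fold models within a
learner and weights across learners; argmax ties break toward the earlier
class in the fixed class order (Normal, BWS1, BWS2, SRS1, AS2, PWS1, PWS2,
FXS).

On the default synthetic cohort the diffuse SRS1 class is the hardest: its
signal lives only in the UMAP global features, and SRS1 test samples are
the typical misclassifications (predicted Normal) — the same failure mode a
heterogeneous genome-wide signature produces in practice.

## Evaluation

Confusion matrices use the clinical-report convention (rows = predicted,
columns = true), so precision is a row statistic and recall a column
statistic; F1 is their harmonic mean, with the 0 convention for degenerate
classes. Accuracy carries the exact Clopper–Pearson interval computed from
Beta quantiles (lower 0 at zero correct, upper 1 at all correct) — the
interval R's `binom.test` reports; Wilson or normal approximations give
different numbers and are not used. Metrics are kept at full precision and
rounded (half away from zero; 2 decimals for per-class cells, 4 for
accuracy) only when rendering reports.

## Numerical and serialization choices

Ages are canonically integer days (years converted at 365.25 d/y, rounded
half away from zero). Reference models serialize to a long TSV (probe, sex,
grid age, μ, σ) plus a JSON sidecar with global stats and diagnostics;
floats are written at full `repr` precision and read back with pandas'
round-trip parser, so reload is bit-exact. Beta matrices, sample sheets and
region maps round-trip through TSV/CSV at 10 significant digits. All
randomness flows from explicit integer seeds through numpy Generators (and
`SeedSequence.spawn` for independent streams); identical seeds give
bit-identical cohorts, fits, embeddings and predictions.

## Known limitations

Single-probe scoring ignores correlation between probes in a locus; the
region sensitivity count is a per-probe tally, not a joint test. The
σ smooth's working-response fit is noticeably noisier than the μ fit at the
age extremes. Grid lookup is nearest-neighbor, not interpolating, so scores
step discretely between adjacent grid ages (at most one day's μ difference
inside the first year). The power simulation's absolute numbers depend
entirely on the assumed ground-truth probe; only orderings and error
control transfer. The classifier is evaluated on synthetic cohorts whose
class structure is, by construction, cleaner than clinical data.
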