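# Methods

This note documents the models implemented in `replaykit`, the assumptions
of the synthetic-data generator, the numerical choices that matter, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Stimuli and the conjunctive code

Building blocks are connected polyominoes on an integer grid (0-based
(row, col), rows growing downward, so "on top" means smaller row indices).
Composition slides one block against another along the relation's axis
until they touch ("drop" contact rule); every block may be used once per
silhouette, and silhouettes are normalised to the origin so equality is
translation-invariant.

The **conjunctive code** of a silhouette is one conjunction per placed
block: `(block id, position signature)`, where the signature is the sorted
tuple of the block's directed role labels over its incident edges (a middle
block in a tower has signature `('bottom', 'top')`). A three-block
silhouette therefore carries exactly three conjunctions, and the canonical
target/reference pair WZ vs ZW shares none. An alternative definition —
one conjunction per *edge endpoint* — would give a middle block two
separate conjunctions; we use the per-block signature because it makes
self-overlap equal the block count and keeps the algebra cancellation
bookkeeping exact.

Overlap metrics: pixel overlap is the maximum Jaccard overlap over all
integer translations (an alternative normalisation by summed pixel counts
is available via `pixel_norm="total"`); size non-overlap combines |Δheight|
and |Δwidth| as a sum (max and L2 available); block overlap is the Jaccard
index of block-id sets, averaged with equal weights over alternative
decompositions when a large silhouette admits several.

**Silhouette-algebra triplets** `+WX − YX + YZ → WZ` (reference ZW) are
enumerated over all ordered distinct block quadruples whose three terms are
present in the stimulus set; targets/references are taken from the set or
composed with zero offset. For four blocks under one relation this yields
24 triplets.

## Synthetic data

Every generator is a pure function of `(GeneratorConfig, arguments)`;
independent random streams are derived from the single seed, so outputs are
bit-reproducible. What the generator emulates, and what it does not:

* **Pattern sets** (`gen_pattern_set`): each conjunction has a fixed random
  code vector (SD `code_sd`, default 1.0) over `n_features` synthetic
  "voxels" (default 100, the size of a cortical searchlight neighbourhood);
  a silhouette's pattern is the sum over its conjunctions, so the algebra
  identity holds *exactly* at zero noise. The visual component projects the
  silhouette's pixel raster (8×8) plus height and width through a random
  linear map (scale `visual_sd`, default 1.0). Noise is white with SD
  `noise_sd` (default 0.5), independent per session (default 3 sessions).
  Real BOLD patterns have spatial autocorrelation, session drifts and
  shared nuisance structure that this does not model; passing recovery
  tests shows estimator correctness, not robustness to those.
* **Localizer epochs** (`gen_localizer`): one random Gaussian sensor
  topography per block class (default 32 sensors), driven by a 100-ms
  half-sine kernel peaking at 200 ms post-onset, plus AR(1) sensor noise
  (ρ = 0.5, SD 2.0). The noise SD is set so that decoding accuracy peaks
  around 0.85–0.9 — saturated accuracy would make the planted latency
  unidentifiable, and real MEG decoding does not saturate. Epochs span
  −500…800 ms so the pre-stimulus null window used by the decoders exists.
* **Task runs** (`gen_task_run`): spontaneous state events are Poisson
  (0.6 events/s per state) over the 3.5-s inference period; planted
  sequences inject a follower event at the stated lag after a fraction
  `rate` of the leader's *spontaneous* events (triples chain at 2×lag).
  Using spontaneous leaders only means two separately planted pairs A→B
  and B→C never concatenate into A→B→C triples — the discriminative
  control for length-3 analysis. Sensor epochs are rendered through the
  same topographies as the localizer, which is what makes classifier
  transfer meaningful. An optional 10-Hz confound oscillation is off by
  default. Follower events pushed past the trial end are counted in
  `series.meta["truncated_events"]`.
* **Behavior** (`gen_behavioral_choices`): Bernoulli draws from the stated
  logistic model.
* **Trial schedules**: per session, exactly half the trials have the
  stable block in the middle (no present-present connection), and the 12
  three-block silhouettes appear equally often; the default is 3 sessions
  of 48 trials.

## Decoding

One L1-penalised logistic classifier per block class, trained at a single
latency (default 200 ms, the localizer decodability peak) with positives =
own-class epochs and negatives = other classes' epochs plus one pre-onset
"null" sample per epoch (window −500…0 ms), which decorrelates the
classifiers. The penalty is given on a lassoglm-style scale; the mapping to
scikit-learn is `C = scale / (penalty · n_samples)` with `scale = 1`,
chosen so the default 0.006 yields sparse but non-empty sensor weights; the
constant is configurable because the original MATLAB parameterisation is
not bit-reproducible here. Sensors are z-scored with localizer statistics
before training and decoding (raw mode available). One-vs-rest
probabilities are deliberately *not* renormalised across states — the
sequenceness framework treats them as independent evidence. Decodability
curves score a held-out epoch as correct iff the true class's classifier
emits the highest probability (ties broken by fixed state order).

## TDLM sequenceness

First level: for each lag Δ (10-ms grid up to 500 ms), each state's series
is regressed on **all four** lagged state series plus an intercept
(multiple regression; a simple pairwise mode exists for oracle and symmetry
checks). Design rows that would straddle a trial boundary are dropped, not
zero-padded. Zero-variance predictors are flagged and their coefficients
set to zero. Probabilities enter raw by default (z-scoring per trial is a
switch).

Second level: per trial — because the role assignment changes every trial —
the vectorised empirical matrix is regressed on the trial's applicable
theoretical matrices plus an all-ones matrix (mean) and the identity
(self-transitions); coefficients are averaged over trials, so trials
lacking a type (present→present on stable-middle trials) contribute
nothing to it. Theoretical matrices are category-based by default
(stable→both presents, etc.); an edge-based variant restricts entries to
blocks actually connected in the silhouette.

**Control bounds**: each sequence type has two controls, built by
substituting the absent block for the source role or the destination role
of the true matrix (the only reading that yields exactly two controls per
type). The statistical bound is the min/max across lags of the
trial-averaged control coefficients, *pooled over all types' controls* —
one bound, in line with the convention of a single significance line for
sequenceness. On null reactivation series the planted-type statistic stays
within this bound in ≈97% of runs and any-type excursions occur in ≲10%
(computed by `experiments.null_sequenceness_calibration`).

Length-3: a third state's series is regressed on all 12 ordered pairwise
sequence products (state i at t−2Δ times state j at t−Δ) while controlling
for all single state series at lags Δ and 2Δ. A planted A→B→C chain gives
a positive, maximal [A→B]→C coefficient at the planted lag. Note that
*unchained* A→B and B→C pairs produce a **negative** coefficient, not
zero: B events that follow A are specifically never followed by C, and the
regression correctly reports that anti-association.

Sliding windows: 1000-ms windows stepped by 10 ms over −500…3500 ms (301
windows; first [−500, 500], last [2500, 3500]); per window the two-level
model is restricted to target samples inside the window (lagged predictors
may reach back within the trial) and averaged over 10–200-ms lags. The
non-overlapping 500-ms variant is `window_ms = step_ms = 500`.

## RSA

Prewhitening multiplies patterns by the inverse square root of a
Ledoit–Wolf shrinkage covariance estimated from condition-mean-removed
residuals (fixed-shrinkage mode available; shrinkage 1 reduces to a global
scaling). Distances are 1 − Pearson r, computed **across sessions only**.

The algebra contrast regresses composite↔target and composite↔reference
distances on a binary conjunctive predictor (reference +0.5, target −0.5)
plus two z-scored visual controls. The pixel control is
`1 − cosine(Σ sign·v(term), v(candidate))` on the full visual feature
vector (raster + height/width): this is the distance a purely visual
pattern code would induce between the composite and the candidate, so any
shared variance between the contrast and visual structure is removed.
(Additive sums of pairwise term-candidate distances — an apparently natural
alternative — have the wrong functional form and leave a small systematic
bias under a visual-only code; we verified the cosine form reduces the
visual-only group effect to t ≈ 0 while leaving the conjunctive effect
unchanged.) The size control is the L1 difference between the signed
height/width combination and the candidate's. Group inference is a
one-sample t over per-subject coefficients, feeding the sign-flip
permutation machinery where maps are involved.

Searchlights use the k nearest features (Euclidean, k = 100 by default) on
the synthetic feature coordinates — a stand-in for geodesic cortical
neighbourhoods, which are out of scope; the statistic inside each
searchlight is unchanged.

The time-resolved variant fits, per time sample, a one-hot GLM (12
silhouette regressors + mean; minimum-norm solve, as the one-hot columns
sum to the mean column), prewhitens the sensor-space coefficient patterns
with Ledoit–Wolf on the GLM residuals, computes pairwise Pearson
similarities between silhouette patterns, and regresses them on z-scored
theoretical similarities (conjunctive overlap counts, pixel overlap,
negative size difference). Significance thresholds are the 2.5th/97.5th
percentiles of coefficients recomputed under random relabelings of the
stimulus conditions (the same permutation applied to every theoretical
matrix, preserving their internal structure), pooled over shuffles and
time points.

## Repetition suppression and behavior

The design columns are computed with the stimulus overlap metrics on
consecutive trial pairs; relational non-overlap is binary (same vs
different relation class), split into small/small, large/large and cross
transitions; block non-overlap is split by current-trial size with
solution-weighted averaging for large silhouettes. Each column is min–max
projected onto [−1, 1] per session (divide-by-max-|value| available); the
projection is affine, so rank order is preserved. First trials of a
session carry no transition regressors; zero-variance columns are dropped
with a warning. The GLM convolves stick functions modulated by each column
with the canonical double-gamma HRF (nilearn's SPM-style kernel; it
emulates but does not bit-match the original toolbox default) and fits by
OLS.

The similarity logistic model is fitted per subject by maximum likelihood
(statsmodels); on perfect separation it falls back to a ridge-penalised
fit with a warning (no standard errors). Group inference is a one-sample t
across subject coefficients.

## Permutation statistics

Sign-flip cluster-mass: one-sample t per feature; suprathreshold features
(two-sided cluster-forming p < 0.001 at df = n−1) are clustered by
adjacency (lattice or k-NN graph on feature coordinates, k = 6 default)
separately for positive and negative effects and scored by mass (sum of
|t|); the null is the maximum cluster mass per draw with independent
per-subject sign flips (default 5000); corrected
p = (1 + #null ≥ mass) / (n_perm + 1), monotone in mass by construction.

Cluster-length: runs of consecutive time points with |t| above the
critical value (2.09 = two-sided p 0.05 at df 19) are compared against the
95th percentile of maximum run lengths under draws that flip *exactly half*
the subjects (default 10000 draws; independent flips available). t uses
the unbiased variance, df = n−1.

Both procedures are calibrated: under Gaussian nulls the empirical
family-wise error over 200 simulations falls within the binomial 95% CI of
0.05 (`experiments.permutation_calibration`; the calibration loops use 300
and 400 permutations per simulation — ample granularity at the 0.05 level
— while the defaults stay 5000/10000).

## Problem sizes and runtimes

The standard validation scale, used by the test suite and the
reproducibility script, is 20 synthetic subjects × 3 sessions × 48 trials
(144 trials/subject), 32 sensors at 100 Hz, 100 pattern features, 40 null
task runs, and 200 calibration simulations per permutation procedure.
These sizes give comfortable statistical power for every planted effect
while keeping a full reproduction run around half a minute on one CPU.
Null sequenceness calibration runs on generated reactivation series with a
small observation-noise floor rather than re-rendering sensors and
re-training decoders per run — the sequenceness statistics are identical in
form, and the planted-recovery path exercises the full chain.

## Known limitations

* The generator's sensor model (random Gaussian topographies, AR(1) noise)
  contains no forward model, artifacts, or realistic spectra; recovery
  results validate the estimators, not preprocessing robustness.
* The 1 − Pearson distance is attenuated by measurement noise; the algebra
  contrast is unbiased under the implemented controls, but absolute
  distance values are scale-dependent.
* Hierarchical (nine-block) stimulus curricula and physical-stability
  reasoning are not modelled; only two-block compounds and three-block
  task silhouettes are first-class.
* The exact L1-penalty scale of the original MATLAB decoders is not
  reproducible; the mapping constant is explicit and configurable.
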