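# replaykit

Analysis toolkit for **compositional neural codes and replay sequenceness**
in decoded MEG/fMRI-like data, with a synthetic-data module that plants
known ground truth so every estimator is validated by parameter recovery.

## The scientific problem

Naturalistic inference is combinatorial: ten bricks already admit
10! = 3,628,800 stacking orders. One way the brain can cope is to represent
compound stimuli *compositionally* — as building blocks bound to relational
positions ("W on top", "Z at the bottom") — and to *test construction
hypotheses* by rapidly replaying block-to-block sequences. This package
implements the analysis stack for both signatures:

* **Silhouette algebra (RSA).** Under a conjunctive code, patterns add:
  `pattern(WX) − pattern(YX) + pattern(YZ) = pattern(WZ)`. The composite on
  the left should be close (1 − Pearson r, cross-session only) to the
  *target* WZ but not to the *reference* ZW, which uses the same blocks in
  swapped relational positions. A GLM tests this contrast while controlling
  for pixel- and size-based visual similarity; searchlight maps and a
  time-resolved variant (one-hot sensor GLM, shuffle-percentile thresholds)
  are included.
* **Repetition suppression.** Parametric designs for fMRI adaptation —
  block-, relation-, pixel- and size-(non)overlap regressors on consecutive
  trials, projected onto [−1, 1] and convolved with a canonical HRF — plus
  the behavioral similarity logistic model
  `p(left) = 1/(1 + e^{−(β₀ + β₁·Diff_pixel + β₂·Diff_size + β₃·Diff_relation + β₄·Diff_basicBBs)})`.
* **Replay sequenceness (TDLM).** L1-regularised one-vs-rest decoders
  trained on localizer epochs yield per-state reactivation probabilities
  `X(t)`. Temporally delayed linear modelling then runs two GLMs: a first
  level per lag Δ, `X_j(t) = Σ_i β_ij(Δ) · X_i(t−Δ) + intercept`, giving an
  empirical transition matrix **B**(Δ); and a second level,
  `vec(B(Δ)) ~ Σ_k z_k · vec(T_k) + mean + identity`, where the theoretical
  matrices `T_k` encode stable→present, present→stable, and
  present→present sequences per trial. Control sequences (absent-block
  substitutions) give the statistical bound; length-3 chains and 1-s
  sliding windows (301 windows over −500…3500 ms) are supported.
* **Permutation statistics.** Sign-flip max-cluster-mass correction for
  feature maps, cluster-length thresholds for time series (critical
  |t| = 2.09 at df = 19), and shuffle-percentile bounds.

## Worked example

Plant a present→stable replay sequence at a 60-ms lag in one synthetic
subject and recover it through the full localizer → decoder → TDLM chain:

```python
import numpy as np
from replaykit import synthetic as syn, decoding as dec, tdlm

cfg = syn.GeneratorConfig(seed=1)
schedule = syn.gen_trial_schedule(cfg, n_sessions=3, trials_per_session=48)
localizer = syn.gen_localizer(cfg)                      # 4 classes x 25 epochs
clf = dec.train_classifiers(localizer, train_time_ms=200.0)
epochs, truth = syn.gen_task_run(cfg, schedule,
                                 planted=[(("present", "stable"), 60.0, 0.8)])
series = dec.decode_timecourse(clf, epochs)             # time x state probs
model = tdlm.SequencenessModel(series, schedule)
start = int(np.nonzero(series.times_ms >= 500)[0][0])   # skip first 500 ms
res = model.fit(target_range=(start, series.trial_len))
print(res.summary())
```

```
Sequenceness (144 trials, lags 10-500 ms)
sequence type            peak lag  peak coef   ctrl lo   ctrl hi  exceeds
stable_to_present            20ms     0.0177   -0.0556    0.0218    False
present_to_stable            50ms     0.1522   -0.0556    0.0218     True
present_to_present          470ms     0.0128   -0.0556    0.0218    False
present_minus_stable         60ms     0.0745   -0.0287    0.0183     True
```

The planted present→stable sequence is the only effect that exceeds the
pooled control-sequence bound, and the present-minus-stable contrast peaks
at the planted 60-ms lag; the two unplanted sequence types stay within the
bound. At the group level (20 synthetic subjects) the recovered peak lag is
exactly 60 ms.

A thin CLI mirrors the pipeline stages:

```bash
replaykit run --recipe replay-recovery --seed 1 --scale 0.2
replaykit simulate --seed 3 --out runs/demo
```

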