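# Methods

## Model

A trial presenting target `T_i` triggers excitatory activation of `T_i` and
inhibitory activation of the two non-presented targets and of the distractor
set.  All activations are tenth-power logistics of `slope · t` with bounds
+1 (presented target), −1 (each non-presented target) and −3 (the distractor
set, which shares a single slope standing in for three distractors).  The
perceived and remembered activation of the same target level share one
slope; they differ only in sign.

The decision variable is the log ratio of the presented target's activation
plus an additive constant (6.0) to the summed inhibitory activations plus
the same constant.  Inhibitory activation *supports* the decision: as the
non-presented alternatives are driven down, the denominator shrinks and the
evidence grows from ≈0.000977 at stimulus onset toward ln 7 ≈ 1.946.  A
response occurs when the evidence reaches the stopping rule β = 1.0.  The
constant 6.0 keeps the denominator positive (the summed inhibitory bounds
are 5) and the threshold reachable; both constraints are enforced at
construction.

Time base: one accumulation cycle is one millisecond, so slopes have units
ms⁻¹ and observed RTs can be substituted directly for `t` during
estimation.  The default continuous solver bisects the monotone evidence
curve to an evidence residual below 1e−9; an integer-cycle scan (t = 0, 1,
2, …) is retained as an oracle and the two agree within 1 ms.  Trials whose
evidence cannot reach β within the 5000 ms horizon raise an explicit error
from `predict_rt`; see "Backfit" below for how the pipeline treats them.

## Trial-to-trial variability

Each trial has one stochastic value `x` shared by all four slope equations:
`slope = logistic(start + swell·x) · 0.023`.  The start parameter sets the
baseline slope level, the swell parameter its noise sensitivity; both are
unbounded logistic arguments with no sign constraints.  Noise sources:

- `gaussian`: standard normal draws;
- `rectangular`: uniform on [−√3, √3], i.e. zero mean and unit variance —
  the variance is not pinned down by any stated convention, so unit variance
  was chosen for comparability with the Gaussian source;
- `rp_noise`: single-trial RP amplitudes of valid (artifact-free) distractor
  trials, multiplied by 1/SD (population SD, per participant and condition).
  The rescaling is scale-only by default; an optional z-score mode also
  centers, but any shift is absorbed by the start parameters during
  estimation, so centering is cosmetic.

When the number of noise values must match the number of correct target
trials, the RP pool is reduced (or extended) to `n` evenly spaced order
statistics of the sorted pool.  This deterministic quantile thinning keeps
the selected set distributionally faithful to the pool, including its
extremes.  Random subsampling was tried first and rejected: it perturbs the
tails of the noise set relative to the generative pool, and the estimation
stage then prefers degenerate saturated-slope solutions that exploit the
mismatch (the objective at the generative parameters becomes *worse* than at
the degenerate point).

Noise values are rank-paired to trials: sorted noise against RT-sorted
trials, smallest `x` to the fastest trial, ties in RT resolved by original
trial order.  Rank pairing fixes the pairing direction, so the sign of the
swell parameters is resolved by estimation rather than by constraint.

## Estimation

Stage one minimizes `Σ_h (β − Evidence(T_i(h), rt_h))²` with observed RTs
substituted for `t`, using Nelder–Mead (xatol = fatol = 1e−8).  The
six-parameter baseline fit (`tstart_1..3, tswell, dstart, dswell`) starts
from (0, 0, 0, 0.5, 0, 0.5); because a single simplex start is unreliable
on this surface, 512 seeded candidate points (half at jitter SD 0.75, half
at 1.5) are probed cheaply and the best six basins are polished, all minima
kept.

Two numerical safeguards shape this stage:

1. **Saturation barrier.** The minimized function adds a quadratic penalty
   for any realized logistic argument beyond ±6.  Slopes must stay strictly
   inside (0, 0.023); outside that range the surface is flat, parameters
   are meaningless, and the resulting fits cannot generalize across
   conditions or even reach threshold at backfit.  Reported objective
   values are the pure residual sums.
2. **Ridge tie-break.** Within one condition, any parameter set reproducing
   the monotone rank-paired noise→RT curve fits equally well, so the
   baseline fit is under-determined along a ridge.  The baseline candidate
   is therefore selected by the total objective across all four conditions
   after the *minimal* per-condition extension (one `dstart` refit per
   filtering condition).  The rule is the same whatever variant is being
   fitted, so every variant carries a bit-identical baseline fit — the
   inhibitory and excitatory variants are the same model at baseline by
   construction.

Variant structure: `inhibition_only` carries the baseline fit and re-fits
`dstart` per filtering condition (9 free parameters); `excitation_only`
re-fits `tstart_1..3` per condition (15).  The `rp` variant regresses the
inhibition-stage `dstart` estimates on condition-mean RP amplitude (OLS,
four points, amplitude as predictor, one link per participant), sets each
condition's `dstart` from the link, and re-estimates
`tstart_1..3, tswell, dswell` at baseline with the linked `dstart` held
fixed (2 + 5 = 7 parameters).  The `pn` variant mirrors this with one link
per target level from the excitation-stage `tstart` estimates and
condition-mean PN amplitude on valid target trials, then re-estimates
`tswell, dstart, dswell` at baseline (6 + 3 = 9).

## Backfit

Stage two inserts the estimates into the slope equations with `t` unknown
and solves trial-by-trial for the time minimizing the squared evidence
residual — by monotonicity, the threshold-crossing time, found by
vectorised bisection.  For a trial whose evidence never reaches β within
the horizon, that minimizer is the horizon itself, so the pipeline backfit
returns `max_cycles` for such trials with a logged count; the evaluation
stage then penalizes the model honestly instead of aborting the run.  Only
correct target trials are fitted and backfitted.

## Evaluation

Each participant's RTs are sorted and cut into 20 consecutive bins of size
⌊n/20⌋, the remainder assigned one-each to the earliest bins (deterministic
and order-stable); bin means are averaged across participants into a group
distribution.  Inter-quantile densities are `P(i) = 50/(RT(i+1) − RT(i))`,
i = 1..19, and observed vs predicted profiles are compared with
`Σ (P_obs − P_pred)²/P_pred` on 17 degrees of freedom.  The df convention
(19 density cells minus two constraints) is isolated in one function so it
can be swapped; nothing in the procedure pins it down uniquely.  Moments
use population (divide-by-n) denominators, dispersion δ is the SD in ms,
and kurtosis is excess (−3 term included).  Dispersion is reported rather
than variance: on this scale a dispersion column of ≈140–160 alongside
means of ≈700 is the natural reading of "variance" columns in this
literature.

## Synthetic data

The generator reproduces the experiment's structure exactly: 11
participants × 4 conditions × 300 trials (150 target, 50 per stimulus; 150
distractor, 50 per stimulus in filtering, 150 of the single 1020 Hz tone at
baseline), targets 962/1000/1040 Hz, distractor sets widening across
filtering conditions, onset-to-onset intervals uniform on 1450–1600 ms.
Single-trial amplitudes are Gaussian around condition means with trial SD
1.0 µV; ~2% of trials are flagged as artifacts, and ~5% of target trials
are marked incorrect (errors are a flag only — error RTs are not modelled).
Optional full epochs (200 samples, 250 Hz, −100..696 ms) embed each
amplitude so that baseline correction plus the 400–600 ms window mean
reproduces it exactly, with a 150 µV spike marking artifact trials.

RTs are simulated only through the model — no measurement noise is added —
so the forward-simulate → backfit roundtrip is exact and every pipeline
stage can be tested against ground truth.  That is also the generator's
main departure from real data: real RTs contain lapses, sequential effects
and measurement noise that the rank-pairing step can only approximate, so
passing tests demonstrate the correctness and internal consistency of the
procedure, not its adequacy for any particular empirical dataset.

Generative defaults (all overridable, serialized into `truth.json`):

- condition-mean RP amplitude 2.0/1.39/0.93/0.5 µV, spaced proportionally
  to the distractor-set frequency ranges of the four conditions (0, 78,
  136, 191 Hz), so amplitude decreases monotonically with salience and the
  baseline→filtering-1 step is the largest;
- `dstart = intercept + 0.7 · RP mean` with intercept ≈ −2.40 (per
  participant ±0.08): the distractor start parameter falls from ≈ −1.0 at
  baseline to ≈ −2.05 at the most salient condition;
- `tstart ≈ (−0.01, −0.05, −0.09)` (per participant ±0.03),
  `tswell = −0.20`, `dswell = −0.35`.

Three structural choices deserve comment.  Swells are negative so that a
larger noise value slows the trial, which makes the generative pairing
agree with the printed rank-pairing convention (smallest `x` ↔ shortest
RT).  The three target start parameters sit close together because rank
pairing pools RTs across targets and presumes target-specific speed
differences are second-order relative to trial noise; the targets are
counterbalanced, well-discriminable tones, so this is also the realistic
regime.  The distractor pathway operates in a lower logistic range than the
targets and carries most of the noise (|dswell| > |tswell|), consistent
with the linking hypothesis that trial-to-trial variability acts through
distractor inhibition; this asymmetry is also what makes the inhibitory and
excitatory variants empirically distinguishable — in a symmetric-pathway
regime the excitation variant can mimic distractor-driven slowing almost
perfectly on rank-paired synthetic curves.  As a consequence of these
choices the simulated condition effects (hundreds of ms between baseline
and the most salient condition) are deliberately larger than the tens of
milliseconds typical of empirical filtering costs: at realistic effect
sizes, model discrimination and ordering recovery at 11 synthetic
participants would sit below the noise floor of the synthetic procedure.

## Numerical choices and degenerate inputs

- Bisection tolerances: 1e−9 on evidence (scalar solver) and on the time
  interval (vectorised backfit); 64 iterations bound the interval below
  1e−12 of the horizon.
- Slope 0 is accepted by the activation functions for degenerate tests;
  production slopes are strictly positive because the logistic never
  reaches 0 or 1.
- Zero quantile spacing yields an infinite density, propagated rather than
  masked; constant amplitude series cannot be rescaled and raise.
- Every stochastic step (design shuffling, amplitude draws, noise draws,
  optimizer restarts) derives a named sub-seed from one master seed, so any
  stage is independently reproducible and a repeated run is bit-identical.

## Known limitations

- The baseline decomposition into excitatory and inhibitory contributions
  is identified only up to the cross-condition tie-break; individual
  parameter values should be interpreted comparatively (orderings, link
  signs), not as point estimates.
- Slow-tail trials are the least constrained: the evidence curve is
  flattest there, so small parameter error produces large predicted-RT
  error, visible as overestimated dispersion in small fits.
- Error trials, false alarms to distractors, sequential effects, and any
  EEG preprocessing beyond epoched amplitudes are out of scope.
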