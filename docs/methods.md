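# Methods

## Model structure

All three learning models are linear time-varying state-space systems on
the trial axis.  On trial `n` the expressed behavior is read out from the
current hidden state, the scalar visual error is computed, and the state is
updated:

```
y_A(n), y_D(n) = C x(n)                    (read-out, degrees)
e(n) = r(n) − (y_A + y_D)   or 0 on error-clamp trials
x(n+1) = D(n) ( A x(n) + b(n) e(n) )
```

`A = diag(a_k)` holds per-state retention factors (unitless, in [0, 1]);
`b(n)` holds per-state error sensitivities (unitless, ≥ 0); `D(n)` is the
identity except on trials flagged `break_after`, where it applies the
set-break retention factors `d_k` (the fraction of the state *retained*
across a 30 s break — the reported `d_fast ≈ 0.06` means near-total loss of
the fast state, which fixes this reading).  Initial states are zero and
baseline trials never enter a fit.

Within one trial the order of operations is: read out with the current
state → compute the error → update the sensitivity (the current trial's
perturbation counts) → state update → break decay if flagged.  The update
order for the sensitivity is a convention; simulation and fitting use the
same convention throughout, so round trips are exact.

Error sensitivity models savings: let `k(n)` be the number of perturbation
trials since the last perturbation sign switch (clamp and zero-perturbation
trials freeze `k`; a sign switch resets it before counting the switch
trial).  Model 1 grows additively, `b = b0 + k·β` per state; model 2 scales
its initial vector, `b = b0·(1 + k·β)` with one shared rate β.  The two
forms coincide up to the parameterization of the increment; the scaled form
keeps model 2 at nine free parameters.  Growth applies on extinction trials
(after the reset); the alternative of freezing growth during extinction is
not observable in the designs shipped here because extinction is short.

Parameter counts: two-state 6 (`a_s, a_f, b_s, b_f, d_s, d_f`); model 1
and the reduced model 2 each 9.  The full 13-parameter model 2 (separate
`d_aim`, `d_acc`, and per-state growth rates) is available through optional
fields on `Model2Params`.

## Experiment reconstructions

The modeled trial axis contains only primary-direction trials; filler
trials along other directions carry no adaptation-relevant error and are
dropped.

* **Alternating-clamp design (exp1)** — 80 baseline trials, a 120-trial
  first perturbation period (+5°), twelve 80-trial periods alternating
  error clamp and perturbation, and a 120-trial final clamp period
  (1280 modeled trials, 7 maximal runs of each type).  One set break falls
  in the middle of every period, so period transitions never coincide with
  breaks.  The published description under-determines the exact layout;
  this reconstruction satisfies the stated period counts, the 120-trial
  first period, and the break-inside-block structure, and every layout
  parameter is overridable in `Exp1Config`.
* **Spontaneous-recovery design (exp2)** — 80 baseline, 420 perturbation
  trials (+5°), 40 extinction trials (−5°), one set break, 100 error-clamp
  trials.  Only the final break is documented; additional
  adaptation-block breaks are configurable.
* **Single-error design (exp3)** — 64 baseline, then 156 `+5°` and 156
  `−5°` jumps, each inserted into a distinct gap between consecutive
  no-jump control trials (624 by default), which guarantees every
  perturbation is isolated by controls on both sides.  Fully reproducible
  from a seed.

## Synthetic saccades

The trace generator produces 1 kHz position/velocity traces for a 15°
movement: vertical velocity follows an asymmetric raised-cosine profile
(20 ms rise, 50 ms fall, matching measured control saccades of roughly
21/54 ms), zero-padded 30 ms on each side.  Horizontal velocity is the sum
of three unit-displacement bumps scaled by the requested components: an
*aim* component proportional to the whole vertical profile, and components
confined to the acceleration or deceleration window.  Each sampled bump is
numerically renormalized so integrated displacement equals the requested
degrees to machine precision.  The acceleration-phase fraction of the
profile's displacement is 20/70 ≈ 0.286.

What this emulates: the displacement decomposition that the analysis
consumes.  What it does not: main-sequence variability, curvature, noise
correlations, blinks, or tracker artifacts — so passing kinematic tests
validates the measurement pipeline, not robustness to real recording
artifacts.

Measurement: traces are filtered with a zero-phase (forward–backward)
3rd-order Butterworth low-pass at 200 Hz (zero-phase because phase lag
would bias the peak-speed timing).  A saccade is detected where speed
exceeds 30 deg/s; onset/offset are then refined by walking each edge out
to a 1 deg/s floor so the slow tails of the profile stay inside the
integration windows (without the refinement the acceleration duration is
under-reported by ~4 ms and the displacement integrals lose a few
hundredths of a degree).  The acceleration window is [onset, peak), the
deceleration window [peak, offset], with the peak-speed sample shared as
the trapezoidal boundary; ties at the peak break to the earliest sample.

The error-clamp landing prediction extrapolates each axis independently
from the state sampled when speed falls below 150 deg/s:
`t* = −v/a`, `landing = x + v t* + ½ a t*²` — exact for
constant-acceleration motion, with residual growing with jerk.

The compensation-onset rule (the original inflection-point procedure is
not described in enough detail to reproduce) is a stated stand-in: the
onset is the first sample from which the pooled response-to-error trace
stays at or above `2 × baseline SD` for at least 10 ms; both constants are
exposed.

## Synthetic cohorts

A participant is a noiseless simulation plus iid Gaussian observation
noise per displacement channel, default SD 0.25° per channel — a typical
saccade endpoint scatter; the effective noise level of the original data
is unpublished, so every recovery analysis reports results as a function
of this sigma.  Cohort heterogeneity jitters the center parameter set on a
transformed scale (logit for rates and fractions, log for sensitivities)
with rejection of constraint-violating draws; the default jitter is 0.1.
All randomness derives from one master seed through spawned
`SeedSequence`s, so cohorts are reproducible across platforms.

## Fitting

The objective is the summed squared residual of predicted vs observed
acceleration- and deceleration-period displacements over all non-baseline
trials (both channels; the scalar two-state model fits total
displacement).  Joint fits sum the objective across two experiments with a
single shared parameter set, which is what breaks the trade-offs a single
design leaves open.

Constraints `a_slow ≥ a_fast` and `b_fast0 ≥ b_slow0` are enforced by
reparameterization (`a_fast = a_slow·u`, `b_slow0 = b_fast0·w`, with
`u, w ∈ [0, 1]`), keeping the search space a box.  Bounds: retention,
break-retention and fraction parameters in [0, 1]; initial sensitivities
in [0, 0.5]; growth rates in [0, 10⁻³] per state (model 1) or [0, 10⁻²]
shared (model 2) — brackets the reported best-fit values by at least an
order of magnitude.

Each restart draws a uniform initial point inside the bounds from a fixed
seed and runs SciPy's trust-region reflective least-squares solver
(`x_scale` set to the box widths; tolerances 10⁻¹²).  The best restart is
polished at tolerance 10⁻¹⁵ and returned with the full restart SSE
spread.  Residuals are clipped at 10⁶ when a candidate destabilizes the
closed loop (large sensitivities make the error feedback expansive), so
divergent restarts fail softly rather than overflow.  Multi-restart
matters: on the full designs roughly half of uniform restarts land in the
divergent region or a local minimum; with 20+ restarts the noiseless
round trip recovers every parameter of both models to machine precision.

Bootstrap confidence intervals resample participants with replacement,
average their series element-wise, refit, and take interior percentiles
(95 % by default).  The reference analysis used 10,000 batches; tests use
much smaller counts since only the machinery, not the published intervals,
can be checked against synthetic data.

## Model comparison and recovery

Least-squares fits are scored with the concentrated Gaussian
log-likelihood `LL = −(n/2)(ln(2π·SSE/n) + 1)` with `n` counting both
channels of every fitted trial; AIC and BIC follow.  With both candidate
models at 9 parameters, LL, AIC and BIC selections coincide.  Ties
(|ΔLL| < 10⁻⁹, or two perfect fits) are reported and split evenly in
confusion tallies.

Parameter recovery simulates noisy data for a cohort of parameter sets,
refits, and correlates true vs recovered values per parameter across the
cohort, batching over noise seeds.  Model recovery simulates from each
model in turn, fits both, and tallies LL selections into a confusion
table.

## Problem sizes and numerical choices in the shipped tests

Fitting-heavy properties run on miniature schedules that preserve the
identifying structure at a fraction of the trial count: a 232-trial
alternating-clamp design (8 set breaks) and a 192-trial
adaptation/extinction/clamp design (2 breaks), with 4–8 restarts and 2–4
recovery batches.  Two choices there are scientific rather than
convenience:

* Model recovery is run on the break-rich alternating-clamp design.
  Set-break decay is the only behavior that separates the coupled
  (model 1) from the decoupled (model 2) break structure; on the
  spontaneous-recovery design alone, model-1-generated data is selected
  as model 2 about half the time — the same weak model-1 recoverability
  the original analysis reported.
* Parameter-recovery correlations at nonzero noise use cohort jitter 0.3
  on the transformed scale.  A correlation needs between-participant
  spread as signal; at the default 0.1 jitter the spread on a mini
  schedule is smaller than the noise-induced estimation error and all
  correlations collapse toward zero regardless of fit quality.

Degenerate inputs: empty schedules, non-contiguous trial indices,
unsatisfiable isolation constraints, zero-SSE likelihoods (+∞ with a
warning), non-decelerating extrapolation, and breaks at series boundaries
all raise or flag explicitly rather than returning silent values.

## Known limitations

* Set-break forgetting is per-event, not per-second; break duration is
  metadata.
* The exp1 layout is a declared reconstruction; analyses that depend on
  exact break placement should treat positions as configurable, not
  ground truth.
* The compensation-onset rule is a documented stand-in for an
  under-specified published procedure.
* Published cohort-level numbers from the original human data (e.g.
  16.5 % spontaneous recovery, −30 % break decay, 73.4 % model-2
  preference) are not reproducible from synthetic data and are treated as
  qualitative orderings only.
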