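# Methods

## Task model

The simulated task is a two-alternative luminance discrimination with
post-decisional stimulus viewing. Frames refresh at 75 Hz (`frame_duration
= 1/75 s`; the often-quoted 13.33 ms is a rounding of this value). Each
frame's luminances are independent Gaussians around the bright/dark means
(142/130), SD 55, truncated at `truncation_sds = 1` SD by rejection
sampling — rejection, not clipping, because clipping would put probability
mass on the truncation bounds and distort the residual distribution.
Luminances are kept continuous; quantising to 8-bit RGB would add structure
that neither the model nor the analyses describe.

Residual evidence is `((bright − dark) − 12) / 110`, where 110 is the
analytic maximum |de-meaned difference| permitted by the truncation box
(verified in tests by corner enumeration). One divisor therefore applies to
every trial and session, the transform is an affine bijection, and residuals
live in [−1, 1] with positive values favouring the correct side. Frame `i`
covers `[i/75, (i+1)/75)` seconds; "first frame" is index 0. Response events
are snapped to frames by flooring (a frame's evidence is on screen for its
whole duration).

## Decision model

A drift-diffusion process accumulates evidence for the correct option
between absorbing bounds 0 and `B`, starting uniformly on `B/2 ± Sz/2`.
Parameters (evidence units unless noted): `B` bound separation; `Sz`
starting-point range; `mu` mean drift (per s); `eta` SD of the internal
across-trial drift component; `s`, `slope` weight and decay rate (per s) of
the external "snapshot" component; `theta` SD of stimulus-driven
within-trial noise; `B_CoM` change-of-mind threshold distance back from the
initial bound; `timeOut` ∈ [0, 1] the fraction of the 1.5 s post-decision
window with active accumulation (truncated abruptly); `tnd`/`tndVar`
mean/SD (s) of the non-decision time, one draw per trial shared by the
initial and change-of-mind response (negative draws resampled);
`stepsize` = 1 ms; endogenous within-trial noise SD fixed at 0.1 as the
scaling unit.

The snapshot term defaults to a sign-symmetric decay toward zero,
`sign(ff)·max(0, s|ff| − slope·t)`: a linear ramp subtracted regardless of
sign (`s·ff − slope·t`, available as `ext_mode="literal"`) would not decay
toward zero for negative first frames, contradicting the "decaying
snapshot" reading. Both modes are exposed; tests and analyses run the
default.

### Numerical scheme

The update is Euler–Maruyama: `dDV = drift·dt + noise·√dt`, the only scheme
whose behaviour is stepsize-independent in the limit. A literal
`noise·dt` mode (`scheme="literal"`) exists for comparison. Stimulus noise
is drawn once per frame (truncated at 1 SD) and held across that frame's
~13 steps so simulated noise aligns one-to-one with stimulus frames for
reverse correlation; each step applies it with weight `1/√(steps in
frame)`, which makes one frame contribute exactly the increment variance an
iid per-step draw of the same marginal would. Without that weight the
effective diffusion would scale with the frame/step ratio and no
frame-rate-independent continuum limit would exist. The resulting effective
diffusion SD is `√(Var[truncN(0,θ,±θ)] + 0.1²)`
(`comddm.model.effective_diffusion_sd`), which the tests use as the
independent input to the analytic Wiener first-passage oracle
(`comddm.wiener`; closed-form absorption probabilities plus the classical
series density, truncated at 1e-12 with a two-consecutive-small-terms
stopping rule because sine zeros annihilate single terms).

A step that reaches or passes a bound counts as a crossing at that step's
end; post-decision accumulation continues from the realized (slightly
overshooting) DV rather than a value clamped to the bound — the overshoot
is O(σ√dt) ≈ 0.006 evidence units and clamping would bias change-of-mind
rates when `B_CoM` is small. Trials whose response time (decision time +
non-decision time) exceeds the 0.8 s deadline are recorded as non-responses
and excluded downstream. The model stops at the first change of mind; it
never emits double changes (the analyses exclude them anyway, and the
underlying model family has a single change-of-mind bound).

Each simulation batch draws per-trial quantities (start point, internal
drift, stimulus frames, non-decision time) from a seeded numpy generator
and the per-step endogenous noise from a numba-internal stream seeded from
the same generator; identical seeds give bit-identical outputs.

### Variants

`coupled`: the snapshot driver is the trial's own frame-0 stimulus noise.
`decoupled`: the driver is a random permutation of those frame-0 values
across trials — the marginal distribution is identical by construction but
independent of the trial's stimulus. `novar`: `eta = s = 0`.

### Driving the model with rendered stimuli

When a luminance stimulus is supplied, its residuals are mapped to model
noise units with a gain that equates their SD with the internally generated
truncated-normal draw (`comddm.model.stimulus_gain`; exactly `√2·θ` at the
default settings). This keeps stimulus-driven and self-generated
simulations on the same effective diffusion, so the frozen preset produces
the same aggregate behaviour in both modes.

## Reverse correlation

Kernels average residual evidence per condition and signed frame bin,
pooled across participants, time-locked to stimulus onset, the initial
response, or the change-of-mind response; each trial contributes only the
frames actually displayed. For the two response-locked kernels, bins backed
by fewer than 100 trials are dropped. Change-of-mind latencies are
median-split per participant × session (midpoint median for even cells;
exact-median ties go to "slow" so splits are reproducible). A span-3
centered moving average (window clipped at the edges) exists for display
only; all statistics run on unsmoothed series. Frame-wise two-sample
t-tests (Student, pooled variance, pooled across participants) are
deliberately uncorrected — they are illustrative flags, not confirmatory
tests.

The focal *first-frame contrast* compares frame-0 evidence signed toward
the initial choice between change and no-change trials **within**
initial-accuracy class (corrected-error vs error; spoilt-correct vs
correct), combined with change-trial-count weights. The within-class
definition is essential: change trials are heavily enriched in errors, and
error trials carry systematically stronger selection on within-trial noise,
so a pooled contrast is confounded by composition and is significantly
positive even under the no-variability model, where the class-matched
contrast is correctly null.

## Behavioural statistics

Exclusions, in order and counted once per trial: no response → more than
one change → change latency < 50 ms → (screen only, report without
excluding by default) initial RT < 150 ms.

Change-of-mind probability is modelled as a logistic mixed model,
`com ~ accuracy + evidence + accuracy:evidence + (1 | participant)`, fit by
maximum likelihood with adaptive Gauss–Hermite quadrature (`comddm.glmm`;
nAGQ = 10 default, 1 = Laplace). statsmodels offers no ML logistic GLMM, so
the likelihood is implemented here and cross-validated against
`lme4::glmer` in the tests. Change-of-mind latency uses statsmodels
`MixedLM` with ML (REML off — likelihood-ratio tests on fixed effects
require ML). Both focal tests are LR tests of the interaction. Evidence is
coded toward the correct side with treatment-coded accuracy (0 = error), so
"support for the initial decision" is the interaction; a
signed-toward-initial-choice coding is available as an option. Latency is
modelled untransformed (its distribution is near-normal, unlike initial
RTs). Non-nested window comparisons (e.g. 0–200 ms vs 200–400 ms mean
evidence) report AIC plus latent-scale marginal/conditional pseudo-R²; no
p-value. Evidence predictors: frame-0 value; pre-response mean over frames
1..(response frame − 1) (the first frame deliberately excluded); window
means over frames whose onsets fall in [a, b), truncated to pre-response
frames (and flagged) when the response lands inside the window.

## Model fitting

The fitting target is the 4-way response-type proportions plus RT quantiles
(0.1, 0.3, 0.5, 0.7, 0.9) for initially-correct and initially-wrong
responses and change-of-mind latency quantiles for corrected errors and
spoilt corrects; cells under 10 trials are dropped with a warning. The loss
simulates the coupled model, summarises identically, and takes the
unweighted RMSE over the concatenated vector (proportions dimensionless,
quantiles in seconds; a weights option exists). Every evaluation re-uses
the same seed — common random numbers make the loss quasi-deterministic,
without which a simplex on a stochastic loss is ill-posed. Nelder–Mead
searches log-transformed positive parameters (logit for `timeOut`); only an
explicitly named free subset is searched, infeasible proposals (e.g.
`B < B_CoM`) are penalised. The recovery experiment frees (mu, B) with the
rest at truth — a scaled identifiability check, not a full 11-parameter
estimation, and its ground truth is placed off the `B = B_CoM` boundary so
the constraint is inactive at the optimum.

## Synthetic study and the frozen preset

The default study is 4 participants × 5 sessions × 1000 trials, stimuli
rendered per session and behaviour generated from per-participant
parameters jittered ±10% (multiplicative) around the preset so participant
random intercepts are non-degenerate; `B_CoM` is clamped to `B` after
jitter. The manifest records every parameter and seed.

The preset (`REFERENCE_OBSERVER`: B=0.15, mu=0.18, Sz=0.04, B_CoM=0.15,
timeOut=0.5, eta=0.07, slope=0.12, s=1.3, theta=0.30, tnd=0.20,
tndVar=0.04) was chosen once by coarse grid search and then frozen. Two
anchors guided it: aggregate behaviour near the reference operating point
of this task family (~24% changes of mind, ~67% initial accuracy, ~2.6%
non-responses) and a snapshot coupling strong enough that the
change-of-mind *speed* interaction is detectable at the study's own scale
(~4k change trials), with a snapshot decay horizon of ~1.7 s. The preset is
a fixture describing a plausible observer, not an estimate of any real
participant.

What the generator does *not* emulate: session-level non-stationarity
(fatigue, learning), lapses and attention fluctuations, left/right response
biases, double changes of mind, non-Gaussian non-decision time, and any
gamma/display nonlinearity. Passing tests therefore certify the pipeline's
internal consistency — that each analysis recovers the structure the
generating model put in, with calibrated false-positive behaviour — not
that real observers obey this model.

## Problem sizes and numerical tolerances

Test and acceptance workloads are sized for a desktop CPU: null-kernel
calibration at 10,000 trials (4 SE bound per frame), Wiener-oracle
equivalence at 50,000 trials (3 binomial SE on choice probability; RT KS
distance at 1 ms bounded by twice the distance at 0.5 ms, testing that
discretisation bias shrinks with the step), variant contrasts at 100,000
trials per variant (bootstrap 95% CIs), mixed-model direction recovery on
~16,000-trial studies with a 200-replicate type-I check on 4 × 320-trial
null studies (acceptance band 2–9% around the nominal 5%), and parameter
recovery from 20,000 trials at 50,000 simulations per loss evaluation
(±15% band on mu and B). Known numerical choices: series truncation 1e-12
in the oracle; quantile estimation by linear interpolation; floor snapping
of lock times; Student (not Welch) frame-wise t-tests; GLMM convergence is
BFGS with a Nelder–Mead polish, and a boundary estimate `sigma → 0` is
legitimate output, not an error.
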