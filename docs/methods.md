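# Methods

This note documents the models and procedures implemented in `oculonback`,
the assumptions behind the synthetic-session generator, the numerical
choices, and what the package's tests do and do not establish.

## Task model

A trial presents `L ∈ {2, 3, 4}` cues drawn uniformly **with replacement**
from four locations (default oblique directions 45°/135°/225°/315°, 12°
eccentricity), each 150 ms long and followed by an 800-ms delay; the
fixation-point (FP) offset after the last delay is the go signal, so cue
onsets are spaced 950 ms apart and `FP_off − first_onset = 950·L` ms.
The rule (1-back: saccade to the last cue; 2-back: to the one-previous cue)
is fixed per trial.  The *required memory set* during delay `k` is the last
cue (1-back) or the last two cues (2-back, duplicates collapsing); the
*extinction location* at cue `k` is the location present in the set during
delay `k−1` but absent after cue `k`.  Same-location repeats therefore
produce no extinction event — extinction is defined on memory content, not
cue identity.  Completed saccades are classified as CORRECT (rule target),
RULE_ERROR (the other of the last two cues), MEM_ERROR_23BACK (an earlier
cue of the trial), or MEM_ERROR_RANDOM (never-cued location); when the last
two cues coincide no rule-error location exists and such trials cannot
contribute rule errors.  Location indices are 0-based; angles are degrees
counterclockwise from rightward; contralateral means the hemifield opposite
the session's recorded hemisphere.  The oblique default was chosen so that
every location lies strictly in one hemifield (a cardinal layout puts two
cues on the vertical midline, which would leave the stimulation conditions
undefined for half the cues); cardinal layouts are fully supported via
`TaskConfig.location_angles`.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, not
biophysics.  Neuron archetypes are piecewise-constant rate models on top of
a baseline (default 5 spikes/s) with an additive gain (default 8 spikes/s):

- **Memory** — elevated throughout every delay whose required set contains
  the preferred location (so elevation lasts one delay under 1-back, two
  under 2-back).
- **Extinction** — 400-ms transient from cue onset whenever that cue makes
  the preferred location's memory obsolete.
- **Visual** — 400-ms transient from every cue onset at the preferred
  location.  Transients are cue-onset aligned so they dominate the early
  half of the following delay.
- **Order** — delay rate scaled by `(k−1)/3`, spanning [0, 1] over serial
  positions 1–4 (the same covariate the encoding model uses).
- **Rule** — tonic gain during 2-back trials; **mixed** archetypes are
  weighted sums; **null** neurons are homogeneous Poisson.

Spikes are drawn by thinning an inhomogeneous Poisson process with
per-segment piecewise-constant bounds (for these profiles the bound equals
the rate, so the draw is exact).

Choice behavior is drawn from per-rule category probabilities whose defaults
reproduce the published error structure of well-trained macaques (rule
errors 1.7 %/3.3 %, 2-3-back errors 2.8 %/4.1 %, random errors 0.2 %/0.4 %,
fixation breaks 5.6 %/7.5 % for 1-back/2-back; reaction times
208 ± 51 ms vs 194 ± 29 ms, clipped to the response window).  Saccade
endpoints sit at the chosen location rotated by an angle drawn from
`Normal(theta_bias_mean[rule], theta_sd)` toward the non-target cue
(defaults +1° for 1-back, −2° for 2-back — i.e. a −3° two-minus-one
difference — with 6° angular and 1° radial scatter).  `theta_sd` is a
generator addition: without angular dispersion the θ distributions would be
degenerate.  Impossible categories fold into their neighbours (no earlier
cue → the 2-3-back mass becomes random; all locations cued → random mass
becomes 2-3-back; identical last two cues → rule-error mass becomes
correct).

Electrical stimulation is modelled causally with three explicit parameters
rather than through the spiking model: early stimulation in the last delay
of a 2-back trial whose last−1 cue is contralateral erases that memory with
probability `stim_p_erase` (default 0.3), redirecting the choice to the most
recent cue; late stimulation in a 1-back trial with a contralateral last cue
erases that cue, redirecting the choice to the one-previous cue.  The
erased-memory flag also truncates the sustained term of Memory neurons tuned
to the erased location at stimulation onset, so neural and behavioral
effects cohere.  Stimulation additionally shortens reaction times (15 ms)
and inflates endpoint scatter (0.5°); the latency shortening is a free
parameter with no mechanistic model behind it.

On rule-error trials the spike trains follow the rule the animal actually
applied (the opposite of the instructed one).  This is the mechanism that
makes a correct-trial-trained decoder predict the future wrong choice; it
contaminates at most a few percent of trials in every other analysis.

Eye traces are 1-kHz samples: Gaussian fixation jitter (SD 0.05°) and a
raised-cosine saccade whose duration scales with amplitude (≈45 ms at 12°,
peak velocity ≈400°/s, far above the 70°/s detection threshold).  The
generator does **not** emulate microsaccades, blinks, drift, spike-waveform
shape, correlated trial-to-trial variability, or non-Poisson firing
statistics — passing recovery tests therefore demonstrates correctness of
the analysis code under the stated model, not robustness to every artifact
of real recordings.

Determinism: a session is a pure function of (configuration, seed); child
seeds are spawned per stage and per neuron, and writing the same bundle
twice produces byte-identical files.

## Behavior analysis

Saccades are detected where the boxcar-smoothed (5 ms) central-difference
velocity exceeds 70°/s and the excursion's total displacement exceeds 6°;
onset/offset are the threshold crossings.  The first post-FP-offset saccade
defines reaction time and endpoint; the chosen location is the *nearest* of
the four cue locations even outside the 4° reward window (the window
governs reward, but the error taxonomy needs a chosen location for every
completed saccade).  Pre-offset saccades are fixation breaks and are
excluded, with their proportion reported, before all other statistics.

θ is the signed angle between the FP→endpoint and FP→goal directions,
positive toward the non-target cue, measured only on correct trials whose
last two cue directions are 90° apart; it is invariant to endpoint
eccentricity.  Session means per rule give Δθ = mean θ(2-back) − mean
θ(1-back); across sessions a one-sample *t* tests Δθ against zero and a
two-sample Kolmogorov–Smirnov test compares the per-session mean
distributions.

Stimulation effects are evaluated for three conditions keyed on the rule and
the hemifield of the last−1 cue (1-back/contra, 2-back/contra,
2-back/ipsi): a per-session 2×2 Fisher exact test (chosen over χ² for small
cells; the screening test family is configurable in principle) plus paired
*t* tests across sessions on error proportion, reaction time and endpoint
accuracy (distance to target).  A condition is "flagged" when its
across-session error increase is significant at α = 0.05 with a positive
delta.

## Spike metrics

The SDF convolves spike times with a unit-integral Gaussian (σ = 20 ms), so
one spike peaks at 1/(σ√2π) ≈ 19.95 spikes/s.  Z-normalization uses the
mean/SD of 100-ms-bin counts over the session's task time; zero-variance
(silent) neurons are flagged and excluded from population averages.  The
task-relatedness screen compares per-trial 400-ms-equivalent counts in the
cue (mean over post-cue windows), delay (mean over all delay epochs),
saccade (0–400 ms post FP offset) and reward (0–400 ms post reward) epochs
with the 400-ms pre-first-cue baseline by Welch's unpaired *t*; a neuron
passes if any epoch has p < 0.05, and neurons recorded for fewer than five
trial blocks are excluded outright.  The saccade/reward windows and the cue
epoch are package constants: the source analyses name the epochs but not
their windows, and the cue epoch mirrors the visual-response criterion used
when neurons were isolated online — without it, purely cue-locked transient
neurons would be invisible to a delay/saccade/reward screen.  Because the
screen is an any-of-four rule, its family-wise false-positive rate is above
the per-test α; the calibration property (type-I ≈ 0.05) is stated and
tested at the single-epoch level, where α is meaningful.

Population summaries measure activity in 150-ms windows stepped by 10 ms,
z-score it, sort neurons by peak time, and report mean ± SEM with the
pre-cue baseline as reference.  Condition differences use paired *t* tests
in 100-ms windows stepped by 20 ms, deliberately uncorrected for multiple
comparisons.  The 2×2 within-subject ANOVA (order × rule) is computed from
per-subject paired contrasts — with two levels per factor each effect has
one numerator df and F equals the squared paired *t* of its contrast, df
(1, n−1); subjects with missing cells are dropped.  statsmodels' `AnovaRM`
serves as an independent oracle in the tests.

## Encoding model

Each delay contributes exactly two observations (early/late 400-ms counts),
and the stacked design has 18 columns: 4 visual + 4 extinction (early), 4
memory (late), and order/rule/bias separately for each epoch model — the
separate order/rule/bias pairs are what reconcile "included in both models"
with the printed total of 18.  Responses are scaled to 0–100 % of the
neuron's maximum epoch count (`scale="raw"` fits raw counts instead), and
the scaled fit is a quasi-Poisson fit with Wald tests and no dispersion
correction.  In 2-back late epochs both remembered locations receive
indicator 1 (duplicates collapse).

**Identification.** Every early row has exactly one visual indicator set, so
the visual block sums to the early bias column and the raw design is rank
deficient by construction.  The fit imposes a sum-to-zero constraint on the
visual block (via an orthonormal reparametrization), making the visual betas
contrasts of early-epoch rate across cue locations — which is exactly what
the directional analysis consumes, and what gives the Wald tests a
well-defined null.  Memory/extinction blocks are only softly collinear with
rule and bias and are left unconstrained.  All-zero columns are dropped and
reported as absent (NaN), never as zero.

**Fitting.** The GLM is fitted by damped IRLS written for this design: each
iteration solves the weighted least-squares step in the minimum-norm sense
and halves the step until the deviance does not increase, so the deviance
history is non-increasing by construction; convergence is a relative
deviance change below 1e-8 within 100 iterations, and non-convergence or
|β| > 20 (separation) flags the fit, which is then left unclassified.
Undamped IRLS limit-cycles on this near-collinear dummy design, which is
why step-halving is built in; statsmodels' GLM on the reparametrized design
is the independent oracle in the tests.  Linear predictors are clipped at
±30 to avoid overflow on degenerate inputs.

**Classification.** A neuron carries a component when any of its betas has
Wald p < 0.05 (the any-of-four rule over location betas implies a
per-component family rate above α, as in the source analyses); it is
directional for visual/extinction/memory when additionally DI > 0.1.  The
DI denominator is Σ|β| (a max-norm variant is available); all four betas are
used, significant or not.  The preferred direction is the summed-vector
angle; the preferred *location* is its nearest of the four task locations;
the contralateral flag compares the preferred angle with the recorded
hemisphere.  Exclusive single-property sets (for population plots) are
neurons with exactly one directional component.

## Rule decoding

Features are the early/late counts of the last two delays (D1, D2) of
correct trials in which the second-to-last cue was at the neuron's
preferred location and the last cue was not ("P-N" reading, matching the
preferred-then-non-preferred population alignment; the opposite "N-P"
reading is a switch).  The preferred location for trial selection is the
snap of the memory-component preferred angle, falling back to the visual
component for memory-non-directional neurons.  Neurons need ≥ 9 qualifying
trials per rule (8 training + ≥ 1 validation).  Per classifier instance,
trials are drawn independently per neuron within rule (pseudo-trials); a
linear SVM (C = 1, features standardized with training-set statistics,
decision-boundary ties resolved to 1-back) is trained on 8 trials per rule
and evaluated on 100 validation draws from the held-out trials; 100
training re-draws give the accuracy distribution, swept over population
sizes.  Controls: epoch-subset variants, label shuffling (training labels
permuted), and per-type exclusion at a fixed population size of 67 with a
two-sample *t* across re-draws.

Error-trial choice probability trains on 10 correct trials per rule and
validates on correct and rule-error trials (all-4-epoch and first-3-epoch
feature sets).  CP is the fraction of training re-draws whose decoded rule
matches the reference — the true rule on correct trials, and on rule-error
trials the rule consistent with the animal's actual choice (the opposite of
the instructed rule).  This actual-choice-consistency definition is a
package decision; the error pools are built from all completed trials
(error trials are too scarce to restrict to P-N sequences), are reused
across draws, and the variability reported comes from the training
re-draws.

## Benchmark suite and problem sizes

`oculonback.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) runs recovery and calibration studies at these
sizes, chosen to give each estimator its design power while keeping a
single-CPU run in the minutes range:

- GLM recovery: one 400-trial session simulated from a known coefficient
  vector chosen inside the identified space (visual block sum-to-zero —
  components outside the row space are not estimable by any method);
  null calibration: 1,000 Poisson replicates on a fixed 400-trial design.
- Neuron-type recovery: two sessions of 20 neurons per archetype
  (memory/extinction/visual + 20 null) at 500 trials — the upper end of
  realistic session lengths, where the baseline window gives the
  task-relatedness screen its intended sensitivity for transient neurons.
- Decoding: one 450-trial session of 100 neurons (20 per archetype across
  memory/extinction/visual/order/null); calibration and 10-vs-50 ordering
  over 20 seeds at 25 training re-draws; type exclusion at n = 67 with 100
  re-draws.  Rule information reaches the features through the memory
  (strongest, both D2 epochs), and extinction (transient, early D2)
  archetypes, so excluding memory neurons must produce the largest drop.
- Behavior: θ-bias recovery over 100 sessions of 600 trials; stimulation
  specificity over 100 experiments of 17 sessions with ~60 trials per
  (condition × stimulation) cell and `stim_p_erase = 0.3`.

## Known limitations

- The rate model is piecewise-constant and Poisson; no adaptation, bursting,
  latency jitter, or rate correlations between neurons.
- The encoding model inherits the intrinsic crosstalk of the task design
  (e.g. memory indicators co-vary with rule under 2-back), so significance
  labels overlap across components exactly as they do in real data; only
  the directional labels are expected to be archetype-specific.
- The screen's any-of-epochs rule has family-wise type-I above α by design.
- Session files hold spike-width as a per-neuron scalar; waveforms are not
  modelled.
- Eye traces are stereotyped; the saccade detector is not exercised against
  blink artifacts or smooth pursuit.
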