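"""Synthetic session generator.

Produces complete sessions -- trials, inhomogeneous-Poisson spike trains,
1-kHz eye traces, simulated choices and stimulation effects -- with the
statistical structure the downstream analyses assume, plus a ground-truth
sidecar so that every analysis stage can be tested as a recovery problem.

Neuron archetypes mirror the response classes seen in lateral prefrontal
cortex during the oculomotor n-back task:

* MEMORY     -- sustained elevation while the preferred location is in the
                required memory set (one delay under 1-back, two under 2-back);
* EXTINCTION -- transient burst when the memory of the preferred location
                becomes obsolete (the memory-update signal);
* VISUAL     -- transient burst after each cue at the preferred location;
* ORDER      -- delay rate scaling with serial cue position;
* RULE       -- tonic offset in 2-back trials;
* MIXED      -- weighted combination of the above; NULL -- baseline only.

Electrical stimulation is modelled causally: with probability
``stim_p_erase`` it erases the memory of a contralateral cue, which both
redirects the behavioral choice and truncates the sustained firing of
MEMORY neurons tuned to the erased location.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np

from .task import (
    ChoiceCategory,
    ChoiceOutcome,
    Rule,
    Stimulation,
    TaskConfig,
    Trial,
    classify_choice,
    extinction_location,
    required_memory_set,
    target_location,
)

__all__ = [
    "Archetype",
    "NeuronSpec",
    "BehaviorSpec",
    "GroundTruth",
    "PiecewiseRate",
    "generate_trials",
    "rate_profile",
    "sample_spikes",
    "simulate_choice",
    "synthesize_eye_trace",
    "generate_session",
    "default_neuron_panel",
]

#: lead time from trial start (recording onset) to the first cue (ms);
#: leaves the 400-ms pre-cue baseline window inside the trial span
PRE_CUE_MS = 500
#: tail after FP offset kept in the trial span (covers saccade + reward epochs)
POST_FP_MS = 1500
#: reward delivery relative to FP offset (target reappearance 400 ms + 500 ms
#: hold + 100 ms) for correct trials
REWARD_AFTER_FP_MS = 1000


class Archetype(str, Enum):
    MEMORY = "memory"
    EXTINCTION = "extinction"
    VISUAL = "visual"
    ORDER = "order"
    RULE = "rule"
    MIXED = "mixed"
    NULL = "null"


#: archetypes whose response is tuned to a cue location
DIRECTIONAL_ARCHETYPES = (Archetype.MEMORY, Archetype.EXTINCTION, Archetype.VISUAL)


@dataclass
class NeuronSpec:
    """Generating parameters of one synthetic neuron."""

    neuron_id: int
    archetype: Archetype
    preferred_location: int = 0
    baseline_rate: float = 5.0          # spikes/s
    gain: float = 8.0                   # spikes/s added by the component
    transient_duration: float = 400.0   # ms, for VISUAL/EXTINCTION bursts
    sustain_flag: bool = True
    mixture_weights: Optional[dict[str, float]] = None   # archetype name -> weight
    spike_width: float = 0.35           # trough-to-peak, ms

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("rates must be non-negative")
        if self.mixture_weights is not None:
            total = sum(self.mixture_weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError("mixture_weights must sum to 1")


def _per_rule(one_back: float, two_back: float) -> dict[Rule, float]:
    return {Rule.ONE_BACK: one_back, Rule.TWO_BACK: two_back}


@dataclass
class BehaviorSpec:
    """Generating parameters of choice behavior and its stimulation effects.

    Defaults reproduce the error structure, reaction times and trajectory
    biases reported for well-trained monkeys: rule errors 1.7 %/3.3 %,
    2/3-back memory errors 2.8 %/4.1 %, random errors 0.2 %/0.4 % and
    fixation breaks 5.6 %/7.5 % in 1-back/2-back trials; RT 208 +/- 51 ms
    vs 194 +/- 29 ms; and a saccade-endpoint angular bias that is smaller
    (more negative, i.e. away from the non-target cue) under 2-back.
    """

    p_rule_error: dict[Rule, float] = field(default_factory=lambda: _per_rule(0.017, 0.033))
    p_mem_23back: dict[Rule, float] = field(default_factory=lambda: _per_rule(0.028, 0.041))
    p_mem_random: dict[Rule, float] = field(default_factory=lambda: _per_rule(0.002, 0.004))
    p_fixation_break: dict[Rule, float] = field(default_factory=lambda: _per_rule(0.056, 0.075))
    rt_mean: dict[Rule, float] = field(default_factory=lambda: _per_rule(208.0, 194.0))
    rt_sd: dict[Rule, float] = field(default_factory=lambda: _per_rule(51.0, 29.0))
    endpoint_radial_sd: float = 1.0          # deg
    theta_bias_mean: dict[Rule, float] = field(default_factory=lambda: _per_rule(1.0, -2.0))
    theta_sd: float = 6.0                    # deg, angular endpoint scatter
    stim_p_erase: float = 0.3
    stim_rt_shortening: float = 15.0         # ms
    stim_accuracy_worsening: float = 0.5     # deg added to radial scatter

    def __post_init__(self) -> None:
        for rule in Rule:
            ps = [
                self.p_rule_error[rule],
                self.p_mem_23back[rule],
                self.p_mem_random[rule],
                self.p_fixation_break[rule],
            ]
            if any(not 0 <= p <= 1 for p in ps):
                raise ValueError("probabilities must lie in [0, 1]")
            if sum(ps) >= 1:
                raise ValueError("per-rule error probabilities must sum to < 1")
            if self.rt_sd[rule] <= 0:
                raise ValueError("rt_sd must be positive")


@dataclass
class GroundTruth:
    """Sidecar recording exactly how a synthetic session was generated."""

    seed: int
    neuron_specs: list[NeuronSpec]
    behavior_spec: BehaviorSpec
    erased_memory: dict[int, Optional[int]] = field(default_factory=dict)  # trial_id -> loc

    def to_dict(self) -> dict:
        def enc(spec):
            d = dataclasses.asdict(spec)
            d["archetype"] = spec.archetype.value
            return d

        b = dataclasses.asdict(self.behavior_spec)
        for key, val in list(b.items()):
            if isinstance(val, dict):
                b[key] = {k.value if isinstance(k, Rule) else k: v for k, v in val.items()}
        return {
            "seed": self.seed,
            "neuron_specs": [enc(s) for s in self.neuron_specs],
            "behavior_spec": b,
            "erased_memory": {str(k): v for k, v in self.erased_memory.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        specs = []
        for s in d["neuron_specs"]:
            s = dict(s)
            s["archetype"] = Archetype(s["archetype"])
            specs.append(NeuronSpec(**s))
        b = dict(d["behavior_spec"])
        for key, val in list(b.items()):
            if isinstance(val, dict):
                b[key] = {Rule(k): v for k, v in val.items()}
        return cls(
            seed=d["seed"],
            neuron_specs=specs,
            behavior_spec=BehaviorSpec(**b),
            erased_memory={int(k): v for k, v in d.get("erased_memory", {}).items()},
        )


# ---------------------------------------------------------------------------
# piecewise-constant rate functions
# ---------------------------------------------------------------------------

class PiecewiseRate:
    """Piecewise-constant firing-rate function of time (spikes/s)."""

    def __init__(self, edges: np.ndarray, rates: np.ndarray):
        edges = np.asarray(edges, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if edges.ndim != 1 or len(edges) != len(rates) + 1:
            raise ValueError("need len(edges) == len(rates) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("negative rate")
        self.edges = edges
        self.rates = rates

    @classmethod
    def from_bumps(
        cls,
        span: tuple[float, float],
        baseline: float,
        bumps: Sequence[tuple[float, float, float]],
    ) -> "PiecewiseRate":
        """Baseline plus additive rectangular bumps (start, end, height) in ms."""
        t0, t1 = span
        cuts = {float(t0), float(t1)}
        for a, b, _ in bumps:
            a, b = max(a, t0), min(b, t1)
            if b > a:
                cuts.update((float(a), float(b)))
        edges = np.array(sorted(cuts))
        rates = np.full(len(edges) - 1, float(baseline))
        mids = (edges[:-1] + edges[1:]) / 2
        for a, b, h in bumps:
            rates[(mids >= a) & (mids < b)] += h
        rates = np.clip(rates, 0.0, None)
        return cls(edges, rates)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(self.rates) - 1)
        out = self.rates[idx]
        out = np.where((t < self.edges[0]) | (t >= self.edges[-1]), 0.0, out)
        return out if out.ndim else float(out)

    def integral(self) -> float:
        """Expected spike count over the full span (rate in spikes/s, time in ms)."""
        return float(np.sum(self.rates * np.diff(self.edges)) / 1000.0)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])


def rate_profile(
    spec: NeuronSpec,
    trial: Trial,
    config: TaskConfig,
    erased_location: Optional[int] = None,
) -> PiecewiseRate:
    """Firing-rate profile of a neuron over one trial's span.

    ``erased_location`` carries the trial's stimulation-induced erasure: the
    sustained MEMORY term for that location terminates at stimulation onset.
    """
    t0 = trial.cue_onsets[0] - PRE_CUE_MS
    t1 = trial.fp_offset_time + POST_FP_MS
    bumps = _component_bumps(spec, trial, config, erased_location, gain=spec.gain)
    return PiecewiseRate.from_bumps((t0, t1), spec.baseline_rate, bumps)


def _component_bumps(spec, trial, config, erased_location, gain):
    if spec.archetype is Archetype.MIXED:
        if not spec.mixture_weights:
            raise ValueError("MIXED archetype requires mixture_weights")
        out = []
        for name, w in spec.mixture_weights.items():
            sub = dataclasses.replace(spec, archetype=Archetype(name), mixture_weights=None)
            out.extend(_component_bumps(sub, trial, config, erased_location, gain * w))
        return out

    cues = trial.cue_locations
    n = trial.n_cues
    delay_start = [trial.cue_onsets[k - 1] + config.cue_duration for k in range(1, n + 1)]
    delay_end = [
        trial.cue_onsets[k] if k < n else trial.fp_offset_time for k in range(1, n + 1)
    ]
    stim_on = trial.stim_onset(config)

    bumps: list[tuple[float, float, float]] = []
    if spec.archetype is Archetype.NULL:
        return bumps
    if spec.archetype is Archetype.MEMORY:
        for k in range(1, n + 1):
            if spec.preferred_location in required_memory_set(trial.rule, cues, k):
                a, b = delay_start[k - 1], delay_end[k - 1]
                if (
                    erased_location == spec.preferred_location
                    and stim_on is not None
                    and b > stim_on
                ):
                    b = max(a, stim_on)
                if b > a:
                    bumps.append((a, b, gain))
    elif spec.archetype is Archetype.EXTINCTION:
        for k in range(1, n + 1):
            if extinction_location(trial.rule, cues, k) == spec.preferred_location:
                on = trial.cue_onsets[k - 1]
                bumps.append((on, on + spec.transient_duration, gain))
    elif spec.archetype is Archetype.VISUAL:
        for k in range(1, n + 1):
            if cues[k - 1] == spec.preferred_location:
                on = trial.cue_onsets[k - 1]
                bumps.append((on, on + spec.transient_duration, gain))
    elif spec.archetype is Archetype.ORDER:
        for k in range(1, n + 1):
            bumps.append((delay_start[k - 1], delay_end[k - 1], gain * order_scalar(k)))
    elif spec.archetype is Archetype.RULE:
        if trial.rule is Rule.TWO_BACK:
            bumps.append((trial.cue_onsets[0], trial.fp_offset_time, gain))
    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {spec.archetype}")
    return bumps


def order_scalar(k: int) -> float:
    """Serial-position covariate for cue k (1-based), spanning [0, 1] over 1-4."""
    return (k - 1) / 3.0


# ---------------------------------------------------------------------------
# spike sampling
# ---------------------------------------------------------------------------

def sample_spikes(
    rate: PiecewiseRate | Callable[[np.ndarray], np.ndarray],
    t_range: tuple[float, float],
    rng: np.random.Generator,
    bound: Optional[float] = None,
) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train by thinning (times in ms).

    For a :class:`PiecewiseRate` the dominating rate is the segment's own
    rate, so every candidate is accepted and the draw is exact; an arbitrary
    callable needs an explicit global ``bound`` (spikes/s).
    """
    t0, t1 = float(t_range[0]), float(t_range[1])
    if not np.isfinite([t0, t1]).all() or t1 < t0:
        raise ValueError("t_range must be finite with t1 >= t0")

    if isinstance(rate, PiecewiseRate):
        segments = [
            (max(a, t0), min(b, t1), r)
            for a, b, r in zip(rate.edges[:-1], rate.edges[1:], rate.rates)
            if min(b, t1) > max(a, t0)
        ]
        rate_fn = rate
    else:
        if bound is None:
            raise ValueError("a callable rate requires an explicit bound")
        segments = [(t0, t1, float(bound))]
        rate_fn = rate

    spikes: list[np.ndarray] = []
    for a, b, lam in segments:
        if lam < 0:
            raise ValueError("negative rate")
        if lam == 0:
            continue
        n = rng.poisson(lam * (b - a) / 1000.0)
        if n == 0:
            continue
        cand = np.sort(rng.uniform(a, b, size=n))
        accept = rng.uniform(0, 1, size=n) * lam <= np.asarray(rate_fn(cand))
        spikes.append(cand[accept])
    if not spikes:
        return np.empty(0)
    return np.sort(np.concatenate(spikes))


# ---------------------------------------------------------------------------
# trials and behavior
# ---------------------------------------------------------------------------

def generate_trials(
    task_config: TaskConfig,
    n_trials: int,
    rule_mix: Optional[dict[Rule, float]] = None,
    stim_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    stim_timing: Stimulation = Stimulation.EARLY_LAST_DELAY,
    recorded_hemisphere: str = "left",
) -> list[Trial]:
    """Sample a session's trial sequence on a common session clock.

    Cue counts are uniform over the configured range and cue locations are
    sampled uniformly with replacement; FP-offset timing therefore cannot be
    predicted from the sequence so far.  ``stim_fraction`` of trials receive
    electrical stimulation at ``stim_timing``, randomly interleaved.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if rule_mix is None:
        rule_mix = {Rule.ONE_BACK: 0.5, Rule.TWO_BACK: 0.5}
    if not rule_mix:
        raise ValueError("rule_mix must not be empty")
    rules = list(rule_mix)
    probs = np.array([rule_mix[r] for r in rules], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("rule_mix probabilities must sum to > 0")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hemimap = task_config.hemifield_map(recorded_hemisphere)
    lo, hi = task_config.cue_count_range
    step = task_config.cue_duration + task_config.delay_duration

    trials = []
    clock = 0
    for i in range(n_trials):
        rule = rules[rng.choice(len(rules), p=probs)]
        n_cues = int(rng.integers(lo, hi + 1))
        locs = rng.integers(0, task_config.n_locations, size=n_cues).tolist()
        first = clock + PRE_CUE_MS
        onsets = [first + k * step for k in range(n_cues)]
        fp_off = onsets[-1] + step
        stim = stim_timing if rng.uniform() < stim_fraction else Stimulation.NONE
        trials.append(
            Trial(
                trial_id=i,
                rule=rule,
                cue_locations=[int(x) for x in locs],
                cue_onsets=onsets,
                fp_offset_time=fp_off,
                stimulation=stim,
                hemifield_map=dict(hemimap),
            )
        )
        clock = fp_off + POST_FP_MS + task_config.intertrial_interval
    return trials


def _wrap_deg(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def simulate_choice(
    trial: Trial,
    behavior_spec: BehaviorSpec,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[ChoiceOutcome, Optional[int]]:
    """Draw one trial's behavioral outcome.

    Returns the outcome plus the erased memory location (or None): early
    stimulation in 2-back trials whose last-1 cue is contralateral erases
    that memory with probability ``stim_p_erase``, redirecting the choice to
    the most recent cue; late stimulation in 1-back trials with a
    contralateral last cue erases that cue's memory, redirecting the choice
    to the one-previous cue.  Stimulation also shortens RT and inflates
    endpoint scatter.
    """
    rule = trial.rule
    cues = trial.cue_locations
    spec = behavior_spec
    stim = trial.stimulation is not Stimulation.NONE

    if rng.uniform() < spec.p_fixation_break[rule]:
        return ChoiceOutcome(None, ChoiceCategory.FIXATION_BREAK), None

    erased: Optional[int] = None
    chosen: Optional[int] = None
    hemi = trial.hemifield_map or {}
    if trial.stimulation is Stimulation.EARLY_LAST_DELAY and rule is Rule.TWO_BACK:
        if hemi.get(cues[-2]) == "contra" and rng.uniform() < spec.stim_p_erase:
            erased, chosen = cues[-2], cues[-1]
    elif trial.stimulation is Stimulation.LATE_LAST_DELAY and rule is Rule.ONE_BACK:
        if hemi.get(cues[-1]) == "contra" and rng.uniform() < spec.stim_p_erase:
            erased, chosen = cues[-1], cues[-2]

    if chosen is None:
        chosen = _draw_choice(trial, spec, rng, config)

    category = classify_choice(rule, cues, chosen)

    rt = float(np.clip(rng.normal(spec.rt_mean[rule], spec.rt_sd[rule]), 80.0,
                       config.max_reaction_time - 20.0))
    if stim:
        rt = max(60.0, rt - spec.stim_rt_shortening)

    endpoint = _draw_endpoint(trial, chosen, spec, config, rng, stim)
    return ChoiceOutcome(chosen, category, reaction_time=rt, endpoint=endpoint), erased


def _draw_choice(trial, spec, rng, config):
    rule, cues = trial.rule, trial.cue_locations
    target = target_location(rule, cues)
    other = cues[-1] if rule is Rule.TWO_BACK else cues[-2]
    earlier = [c for c in cues[:-2] if c not in (target, other)]
    never = [l for l in range(config.n_locations) if l not in cues]

    # residual categorical draw; impossible categories fold into neighbours
    p_rule = spec.p_rule_error[rule] if other != target else 0.0
    p_23, p_rand = spec.p_mem_23back[rule], spec.p_mem_random[rule]
    if not earlier:
        p_rand += p_23
        p_23 = 0.0
    if not never:
        p_23 += p_rand
        p_rand = 0.0
        if not earlier:
            p_23 = 0.0
    u = rng.uniform()
    if u < p_rule:
        return other
    u -= p_rule
    if u < p_23:
        return earlier[rng.integers(len(earlier))]
    u -= p_23
    if u < p_rand:
        return never[rng.integers(len(never))]
    return target


def _draw_endpoint(trial, chosen, spec, config, rng, stim):
    angles = config.location_angles
    goal_angle = angles[chosen]
    last, prev = trial.cue_locations[-1], trial.cue_locations[-2]
    nontarget = prev if trial.rule is Rule.ONE_BACK else last
    # sign convention: positive theta rotates the endpoint toward the
    # non-target cue's direction
    diff = _wrap_deg(angles[nontarget] - goal_angle)
    direction = np.sign(diff) if abs(diff) not in (0.0, 180.0) else rng.choice([-1.0, 1.0])
    theta = rng.normal(spec.theta_bias_mean[trial.rule], spec.theta_sd)
    radial_sd = spec.endpoint_radial_sd + (spec.stim_accuracy_worsening if stim else 0.0)
    r = max(0.5, config.eccentricity + rng.normal(0.0, radial_sd))
    ang = np.deg2rad(goal_angle + direction * theta)
    return (float(r * np.cos(ang)), float(r * np.sin(ang)))


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

def synthesize_eye_trace(
    trial: Trial,
    outcome: ChoiceOutcome,
    behavior_spec: BehaviorSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    fixation_sd: float = 0.05,
) -> np.ndarray:
    """1-kHz eye-position samples for one trial: columns (t_ms, x_deg, y_deg).

    Fixation-centred Gaussian jitter until FP offset + RT, then a saccade
    with a raised-cosine position profile (peak velocity well above the
    70 deg/s detection threshold for 12-deg amplitudes) landing on the
    outcome's endpoint, then steady fixation at the endpoint.
    """
    t0 = trial.cue_onsets[0] - PRE_CUE_MS
    t1 = trial.fp_offset_time + POST_FP_MS
    t = np.arange(t0, t1, 1.0)
    x = rng.normal(0.0, fixation_sd, size=len(t))
    y = rng.normal(0.0, fixation_sd, size=len(t))

    if outcome.category is ChoiceCategory.NO_RESPONSE:
        return np.column_stack([t, x, y])

    if outcome.category is ChoiceCategory.FIXATION_BREAK:
        onset = trial.fp_offset_time - float(rng.uniform(150, 500))
        loc = int(rng.integers(config.n_locations))
        end = np.array(config.location_xy(loc))
    else:
        if outcome.endpoint is None or outcome.reaction_time is None:
            raise ValueError("completed outcome needs endpoint and reaction time")
        onset = trial.fp_offset_time + float(outcome.reaction_time)
        end = np.array(outcome.endpoint)

    amp = float(np.hypot(*end))
    dur = max(25.0, 15.0 + 2.5 * amp)       # ms; main-sequence-like scaling
    s = np.clip((t - onset) / dur, 0.0, 1.0)
    frac = (1.0 - np.cos(np.pi * s)) / 2.0   # raised-cosine position profile
    x = x + frac * end[0]
    y = y + frac * end[1]
    return np.column_stack([t, x, y])


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def default_neuron_panel(
    n_per_archetype: int = 4,
    archetypes: Sequence[Archetype] = (
        Archetype.MEMORY,
        Archetype.EXTINCTION,
        Archetype.VISUAL,
        Archetype.ORDER,
        Archetype.RULE,
        Archetype.NULL,
    ),
    baseline_rate: float = 5.0,
    gain: float = 8.0,
    n_locations: int = 4,
) -> list[NeuronSpec]:
    """A balanced panel of neuron specs cycling preferred locations."""
    specs = []
    nid = 0
    for arch in archetypes:
        for j in range(n_per_archetype):
            specs.append(
                NeuronSpec(
                    neuron_id=nid,
                    archetype=arch,
                    preferred_location=j % n_locations,
                    baseline_rate=baseline_rate,
                    gain=gain,
                )
            )
            nid += 1
    return specs


def generate_session(
    task_config: TaskConfig,
    n_trials: int,
    neuron_specs: Sequence[NeuronSpec],
    behavior_spec: Optional[BehaviorSpec] = None,
    seed: int = 0,
    recorded_hemisphere: str = "left",
    stim_fraction: float = 0.0,
    stim_timing: Stimulation = Stimulation.EARLY_LAST_DELAY,
    rule_mix: Optional[dict[Rule, float]] = None,
    with_eye: bool = True,
    session_id: str = "synthetic",
    rule_error_swaps_activity: bool = True,
):
    """Generate a complete synthetic session.

    Returns a :class:`~oculonback.io.SessionBundle` whose ``truth`` field is
    the :class:`GroundTruth` sidecar.  Identical arguments (including seed)
    regenerate an identical session.

    With ``rule_error_swaps_activity`` (default), spike trains on rule-error
    trials follow the rule the animal actually applied (the opposite of the
    instructed one), so delay activity predicts the future wrong choice --
    the mechanism behind above-chance error-trial choice probability.
    """
    from .io import SessionBundle, spikes_to_frame

    behavior_spec = behavior_spec or BehaviorSpec()
    ss = np.random.SeedSequence(seed)
    trial_seed, choice_seed, eye_seed, spike_seed = ss.spawn(4)

    trials = generate_trials(
        task_config,
        n_trials,
        rule_mix=rule_mix,
        stim_fraction=stim_fraction,
        seed=np.random.default_rng(trial_seed),
        stim_timing=stim_timing,
        recorded_hemisphere=recorded_hemisphere,
    )

    choice_rng = np.random.default_rng(choice_seed)
    outcomes, erased = [], {}
    for tr in trials:
        out, er = simulate_choice(tr, behavior_spec, task_config, choice_rng)
        outcomes.append(out)
        erased[tr.trial_id] = er

    eye = None
    if with_eye:
        eye_rng = np.random.default_rng(eye_seed)
        chunks = [
            synthesize_eye_trace(tr, out, behavior_spec, task_config, eye_rng)
            for tr, out in zip(trials, outcomes)
        ]
        eye = np.concatenate(chunks, axis=0)

    spike_trials = []
    for tr, out in zip(trials, outcomes):
        if (
            rule_error_swaps_activity
            and out.category is ChoiceCategory.RULE_ERROR
            and erased[tr.trial_id] is None
        ):
            other = Rule.TWO_BACK if tr.rule is Rule.ONE_BACK else Rule.ONE_BACK
            spike_trials.append(dataclasses.replace(tr, rule=other))
        else:
            spike_trials.append(tr)

    spike_rngs = [np.random.default_rng(s) for s in spike_seed.spawn(len(neuron_specs))]
    spike_rows = []
    for spec, nrng in zip(neuron_specs, spike_rngs):
        for tr in spike_trials:
            prof = rate_profile(spec, tr, task_config, erased_location=erased[tr.trial_id])
            ts = sample_spikes(prof, prof.span, nrng)
            for t in ts:
                spike_rows.append((spec.neuron_id, float(t)))

    truth = GroundTruth(
        seed=seed,
        neuron_specs=list(neuron_specs),
        behavior_spec=behavior_spec,
        erased_memory=erased,
    )
    return SessionBundle(
        meta={
            "session_id": session_id,
            "recorded_hemisphere": recorded_hemisphere,
            "task_config": task_config.to_dict(),
            "seed": seed,
        },
        trials=trials,
        outcomes=outcomes,
        spikes=spikes_to_frame(spike_rows),
        neurons=_neuron_meta(neuron_specs, n_trials),
        eye=eye,
        truth=truth,
    )


def _neuron_meta(neuron_specs, n_trials, trials_per_block: int = 20):
    import pandas as pd

    return pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in neuron_specs],
            "spike_width_ms": [s.spike_width for s in neuron_specs],
            "n_blocks": [max(1, n_trials // trials_per_block)] * len(neuron_specs),
        }
    )
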