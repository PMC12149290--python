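"""Saccade detection and behavioral statistics.

Covers detection of saccades from 1-kHz eye traces (velocity > 70 deg/s and
displacement > 6 deg), scoring of trials into the behavioral error taxonomy,
the signed trajectory angle theta (positive toward the non-target cue,
measured on correct trials whose last two cues are 90 deg apart), and the
stimulation-effect statistics comparing error rates, reaction times and
endpoint accuracy between stimulated and control trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import (
    ChoiceCategory,
    ChoiceOutcome,
    Rule,
    Stimulation,
    TaskConfig,
    Trial,
    classify_choice,
    target_location,
)

__all__ = [
    "SaccadeEvent",
    "detect_saccades",
    "score_trial",
    "theta_angle",
    "theta_records",
    "theta_session_stats",
    "theta_group_test",
    "theta_distribution_test",
    "condition_table",
    "stimulation_effect_test",
    "outcome_summary",
]

VELOCITY_THRESHOLD = 70.0   # deg/s
AMPLITUDE_THRESHOLD = 6.0   # deg, total displacement of the excursion
SMOOTH_MS = 5               # boxcar width applied to the velocity trace


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float                    # ms
    offset: float                   # ms
    start: tuple[float, float]      # deg
    end: tuple[float, float]        # deg
    amplitude: float                # deg
    peak_velocity: float            # deg/s


def detect_saccades(eye: np.ndarray) -> list[SaccadeEvent]:
    """Detect saccades in a uniform 1-kHz eye trace (columns t, x, y).

    An event is an excursion where the smoothed angular eye velocity exceeds
    70 deg/s and whose total displacement exceeds 6 deg; onset and offset
    are the threshold crossings.
    """
    eye = np.asarray(eye, dtype=float)
    if eye.ndim != 2 or eye.shape[1] != 3 or len(eye) < 5:
        raise ValueError("eye trace must be an (n, 3) array of t, x, y with n >= 5")
    t = eye[:, 0]
    dt = np.diff(t)
    if not np.allclose(dt, 1.0, atol=1e-6):
        raise ValueError("non-uniform sampling: expected 1-kHz (1-ms) samples")

    x, y = eye[:, 1], eye[:, 2]
    # central differences (deg/ms -> deg/s), then a short boxcar to tame
    # sample noise; SMOOTH_MS is a documented constant, not a task parameter
    vx = np.gradient(x, t) * 1000.0
    vy = np.gradient(y, t) * 1000.0
    speed = np.hypot(vx, vy)
    kernel = np.ones(SMOOTH_MS) / SMOOTH_MS
    speed = np.convolve(speed, kernel, mode="same")

    above = speed > VELOCITY_THRESHOLD
    events: list[SaccadeEvent] = []
    idx = np.flatnonzero(np.diff(above.astype(int)))
    starts = [i + 1 for i in idx if not above[i]]
    ends = [i + 1 for i in idx if above[i]]
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    for s, e in zip(starts, ends):
        disp = float(np.hypot(x[e - 1] - x[s], y[e - 1] - y[s]))
        if disp <= AMPLITUDE_THRESHOLD:
            continue
        events.append(
            SaccadeEvent(
                onset=float(t[s]),
                offset=float(t[e - 1]),
                start=(float(x[s]), float(y[s])),
                end=(float(x[e - 1]), float(y[e - 1])),
                amplitude=disp,
                peak_velocity=float(speed[s:e].max()),
            )
        )
    return events


def score_trial(trial: Trial, eye: np.ndarray, config: TaskConfig) -> ChoiceOutcome:
    """Classify one trial's behavior from its eye trace.

    The first saccade after FP offset defines the reaction time and endpoint;
    the chosen location is the nearest of the four cue locations to the
    endpoint (the 4-deg window governs reward, not the error taxonomy).
    A suprathreshold saccade before FP offset is a fixation break; no saccade
    within the allowed reaction time is a no-response trial.
    """
    if eye is None or len(eye) == 0:
        raise ValueError("missing eye data for trial scoring")
    events = detect_saccades(eye)
    fp_off = trial.fp_offset_time
    for ev in events:
        if trial.cue_onsets[0] <= ev.onset < fp_off:
            return ChoiceOutcome(None, ChoiceCategory.FIXATION_BREAK)
    for ev in events:
        if fp_off <= ev.onset <= fp_off + config.max_reaction_time:
            endpoint = ev.end
            xy = np.array([config.location_xy(l) for l in range(config.n_locations)])
            dists = np.hypot(xy[:, 0] - endpoint[0], xy[:, 1] - endpoint[1])
            chosen = int(np.argmin(dists))
            category = classify_choice(trial.rule, trial.cue_locations, chosen)
            return ChoiceOutcome(
                chosen, category, reaction_time=float(ev.onset - fp_off), endpoint=endpoint
            )
    return ChoiceOutcome(None, ChoiceCategory.NO_RESPONSE)


# ---------------------------------------------------------------------------
# trajectory angle theta
# ---------------------------------------------------------------------------

def _wrap_deg(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def theta_angle(
    endpoint: tuple[float, float], goal_angle: float, nontarget_angle: float
) -> float:
    """Signed angle (deg) between the endpoint and goal directions.

    Positive values indicate a shift of the endpoint toward the non-target
    cue direction.  Requires the goal and non-target directions to be 90 deg
    apart (the inclusion rule for this measurement).
    """
    sep = abs(_wrap_deg(nontarget_angle - goal_angle))
    if not np.isclose(sep, 90.0):
        raise ValueError("theta is defined for goal/non-target separations of 90 deg")
    ex, ey = endpoint
    if np.hypot(ex, ey) == 0:
        raise ValueError("zero-length endpoint vector")
    ep_angle = np.rad2deg(np.arctan2(ey, ex))
    delta = _wrap_deg(ep_angle - goal_angle)
    toward = np.sign(_wrap_deg(nontarget_angle - goal_angle))
    return float(delta * toward)


def theta_records(
    trials: Sequence[Trial],
    outcomes: Sequence[ChoiceOutcome],
    config: TaskConfig,
) -> pd.DataFrame:
    """Per-trial theta table with inclusion flags.

    A trial is included when it is correct and the directions of its last
    two cues differ by 90 deg.
    """
    recs = []
    for tr, out in zip(trials, outcomes):
        a_last = config.location_angles[tr.cue_locations[-1]]
        a_prev = config.location_angles[tr.cue_locations[-2]]
        ninety = np.isclose(abs(_wrap_deg(a_last - a_prev)), 90.0)
        included = bool(ninety and out.category is ChoiceCategory.CORRECT
                        and out.endpoint is not None)
        theta = np.nan
        if included:
            goal = config.location_angles[target_location(tr.rule, tr.cue_locations)]
            nt_loc = tr.cue_locations[-1] if tr.rule is Rule.TWO_BACK else tr.cue_locations[-2]
            theta = theta_angle(out.endpoint, goal, config.location_angles[nt_loc])
        recs.append(
            {"trial_id": tr.trial_id, "rule": tr.rule.value, "theta": theta,
             "included": included}
        )
    return pd.DataFrame(recs)


def theta_session_stats(records: pd.DataFrame) -> dict:
    """Per-session mean theta by rule and their difference (2-back - 1-back)."""
    out: dict[str, float] = {}
    for rule in Rule:
        sel = records[(records["rule"] == rule.value) & records["included"]]
        out[f"mean_theta_{rule.value}"] = float(sel["theta"].mean()) if len(sel) else np.nan
    out["delta_theta"] = out["mean_theta_2-back"] - out["mean_theta_1-back"]
    return out


def theta_group_test(deltas: Sequence[float]) -> tuple[float, float]:
    """One-sample t test of per-session delta-theta against zero."""
    d = np.asarray(deltas, dtype=float)
    d = d[~np.isnan(d)]
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)


def theta_distribution_test(theta_1b: Sequence[float], theta_2b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test on per-session mean theta values."""
    res = stats.ks_2samp(np.asarray(theta_1b, float), np.asarray(theta_2b, float))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# stimulation-effect statistics
# ---------------------------------------------------------------------------

#: the three analyzed stimulus configurations: (rule, hemifield of last-1 cue)
STIM_CONDITIONS = (
    (Rule.ONE_BACK, "contra"),
    (Rule.TWO_BACK, "contra"),
    (Rule.TWO_BACK, "ipsi"),
)


def condition_table(
    trials: Sequence[Trial],
    outcomes: Sequence[ChoiceOutcome],
    config: TaskConfig,
    session_id: str = "s0",
) -> pd.DataFrame:
    """Long-format completed-trial table for the stimulation analysis.

    Fixation breaks and no-response trials are excluded up front (their
    proportion is reported by :func:`outcome_summary`).  ``accuracy`` is the
    distance (deg) from the saccade endpoint to the rule-defined target.
    """
    recs = []
    for tr, out in zip(trials, outcomes):
        if out.category in (ChoiceCategory.FIXATION_BREAK, ChoiceCategory.NO_RESPONSE):
            continue
        hemi = (tr.hemifield_map or {}).get(tr.cue_locations[-2], "mid")
        acc = np.nan
        if out.endpoint is not None:
            tx, ty = config.location_xy(target_location(tr.rule, tr.cue_locations))
            acc = float(np.hypot(out.endpoint[0] - tx, out.endpoint[1] - ty))
        recs.append(
            {
                "session_id": session_id,
                "trial_id": tr.trial_id,
                "rule": tr.rule.value,
                "last1_hemi": hemi,
                "stim": tr.stimulation is not Stimulation.NONE,
                "error": out.category is not ChoiceCategory.CORRECT,
                "rt_ms": out.reaction_time,
                "accuracy_deg": acc,
            }
        )
    return pd.DataFrame(recs)


def stimulation_effect_test(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Stimulation-vs-control statistics for the three analyzed conditions.

    Per condition: a per-session 2x2 Fisher exact test of error counts
    (stim x error) and, across sessions, paired t tests on error proportion,
    reaction time and endpoint accuracy.  Conditions with an empty cell in a
    session skip that session with a warning.
    """
    rows = []
    for rule, hemi in STIM_CONDITIONS:
        sub = table[(table["rule"] == rule.value) & (table["last1_hemi"] == hemi)]
        per_session = []
        for sid, g in sub.groupby("session_id"):
            stim, ctrl = g[g["stim"]], g[~g["stim"]]
            if len(stim) == 0 or len(ctrl) == 0:
                warnings.warn(
                    f"condition ({rule.value}, {hemi}) has an empty cell in "
                    f"session {sid}; skipped",
                    stacklevel=2,
                )
                continue
            tab2x2 = [
                [int(stim["error"].sum()), int((~stim["error"]).sum())],
                [int(ctrl["error"].sum()), int((~ctrl["error"]).sum())],
            ]
            _, fisher_p = stats.fisher_exact(tab2x2)
            per_session.append(
                {
                    "session_id": sid,
                    "err_stim": stim["error"].mean(),
                    "err_ctrl": ctrl["error"].mean(),
                    "rt_stim": stim["rt_ms"].mean(),
                    "rt_ctrl": ctrl["rt_ms"].mean(),
                    "acc_stim": stim["accuracy_deg"].mean(),
                    "acc_ctrl": ctrl["accuracy_deg"].mean(),
                    "fisher_p": fisher_p,
                }
            )
        row = {"rule": rule.value, "last1_hemi": hemi, "n_sessions": len(per_session)}
        if per_session:
            ps = pd.DataFrame(per_session)
            row["error_delta"] = float((ps["err_stim"] - ps["err_ctrl"]).mean())
            row["rt_delta_ms"] = float((ps["rt_stim"] - ps["rt_ctrl"]).mean())
            row["accuracy_delta_deg"] = float((ps["acc_stim"] - ps["acc_ctrl"]).mean())
            for name, a, b in (
                ("error", ps["err_stim"], ps["err_ctrl"]),
                ("rt", ps["rt_stim"], ps["rt_ctrl"]),
                ("accuracy", ps["acc_stim"], ps["acc_ctrl"]),
            ):
                if len(ps) > 1 and np.isfinite(a).all() and np.isfinite(b).all():
                    t, p = stats.ttest_rel(a, b)
                else:
                    t, p = np.nan, np.nan
                row[f"{name}_t"] = float(t)
                row[f"{name}_p"] = float(p)
            row["error_significant"] = bool(
                row["error_p"] < alpha and row["error_delta"] > 0
            ) if np.isfinite(row["error_p"]) else False
            row["n_sig_sessions_fisher"] = int((ps["fisher_p"] < alpha).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_summary(
    trials: Sequence[Trial], outcomes: Sequence[ChoiceOutcome]
) -> dict:
    """Per-session outcome accounting: category rates by rule and RT stats.

    Fixation-break proportion is reported against all trials; choice-category
    rates are computed over completed trials only (after exclusion).
    """
    out: dict[str, float] = {}
    for rule in Rule:
        cats = [o.category for t, o in zip(trials, outcomes) if t.rule is rule]
        n_all = len(cats)
        out[f"n_trials_{rule.value}"] = n_all
        if n_all == 0:
            continue
        fb = sum(c is ChoiceCategory.FIXATION_BREAK for c in cats)
        out[f"p_fixation_break_{rule.value}"] = fb / n_all
        completed = [
            c for c in cats
            if c not in (ChoiceCategory.FIXATION_BREAK, ChoiceCategory.NO_RESPONSE)
        ]
        n_c = max(1, len(completed))
        for cat in (
            ChoiceCategory.CORRECT,
            ChoiceCategory.RULE_ERROR,
            ChoiceCategory.MEM_ERROR_23BACK,
            ChoiceCategory.MEM_ERROR_RANDOM,
        ):
            out[f"p_{cat.value}_{rule.value}"] = sum(c is cat for c in completed) / n_c
        rts = [
            o.reaction_time
            for t, o in zip(trials, outcomes)
            if t.rule is rule and o.category is ChoiceCategory.CORRECT
            and o.reaction_time is not None
        ]
        out[f"rt_mean_{rule.value}"] = float(np.mean(rts)) if rts else np.nan
        out[f"rt_sd_{rule.value}"] = float(np.std(rts, ddof=1)) if len(rts) > 1 else np.nan
    return out
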