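"""Session directory format: readers, writers and the in-memory bundle.

A session is a directory of plain-text files::

    meta.json     session id, recorded hemisphere, task configuration, seed
    trials.csv    trial_id, rule, n_cues, cue_loc_1..4, cue_onset_1..4,
                  fp_offset, stim, category, chosen_location, rt_ms,
                  endpoint_x, endpoint_y
    spikes.csv    neuron_id, t_ms          (session clock, ms)
    neurons.csv   neuron_id, spike_width_ms, n_blocks
    eye.csv       t_ms, x_deg, y_deg       (1-kHz samples; optional)
    truth.json    generator ground truth   (synthetic sessions only)

Times are milliseconds on a session-relative clock, angles degrees,
location indices 0-based.  Writing is deterministic: the same bundle always
produces byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import POST_FP_MS, GroundTruth
from .task import ChoiceCategory, ChoiceOutcome, Rule, Stimulation, TaskConfig, Trial

__all__ = ["SessionBundle", "read_session", "write_session", "SessionFormatError",
           "spikes_to_frame", "outcomes_to_frame", "trials_to_frame"]

MAX_CUES = 4
_FLOAT_FMT = "%.6f"


class SessionFormatError(ValueError):
    """A session file violates the documented schema."""


@dataclass
class SessionBundle:
    """One session held in memory: trials, spikes, neurons, eye data, truth."""

    meta: dict
    trials: list[Trial]
    outcomes: list[ChoiceOutcome]
    spikes: pd.DataFrame                 # columns: neuron_id, t_ms
    neurons: pd.DataFrame                # columns: neuron_id, spike_width_ms, n_blocks
    eye: Optional[np.ndarray] = None     # columns: t_ms, x_deg, y_deg
    truth: Optional[GroundTruth] = None

    @property
    def task_config(self) -> TaskConfig:
        return TaskConfig.from_dict(self.meta["task_config"])

    @property
    def recorded_hemisphere(self) -> str:
        return self.meta["recorded_hemisphere"]

    def spike_times(self, neuron_id: int) -> np.ndarray:
        sub = self.spikes[self.spikes["neuron_id"] == neuron_id]
        return np.sort(sub["t_ms"].to_numpy(dtype=float))

    @property
    def neuron_ids(self) -> list[int]:
        return [int(x) for x in self.neurons["neuron_id"]]

    def session_span(self) -> tuple[float, float]:
        return 0.0, float(max(t.fp_offset_time for t in self.trials) + POST_FP_MS)

    def validate(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise SessionFormatError("duplicate trial_id in trials table")
        if len(self.outcomes) != len(self.trials):
            raise SessionFormatError("outcome count != trial count")
        if self.recorded_hemisphere not in ("left", "right"):
            raise SessionFormatError("recorded_hemisphere must be 'left' or 'right'")
        lo, hi = self.session_span()
        if len(self.spikes):
            t = self.spikes["t_ms"].to_numpy(dtype=float)
            bad = (t < lo - 1e9) | (t > hi)
            if bad.any():
                nrn = self.spikes["neuron_id"].to_numpy()[bad][0]
                raise SessionFormatError(
                    f"spike timestamp outside session span for neuron {nrn}"
                )
        if self.eye is not None and len(self.eye):
            if self.eye[:, 0].max() > hi:
                raise SessionFormatError("eye sample timestamp outside session span")


# ---------------------------------------------------------------------------
# frame conversions
# ---------------------------------------------------------------------------

def spikes_to_frame(rows: Sequence[tuple[int, float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["neuron_id", "t_ms"])
    df["neuron_id"] = df["neuron_id"].astype(int) if len(df) else df["neuron_id"]
    return df.sort_values(["neuron_id", "t_ms"], kind="mergesort").reset_index(drop=True)


def trials_to_frame(trials: Sequence[Trial], outcomes: Sequence[ChoiceOutcome]) -> pd.DataFrame:
    recs = []
    for tr, out in zip(trials, outcomes):
        rec = {"trial_id": tr.trial_id, "rule": tr.rule.value, "n_cues": tr.n_cues}
        for j in range(MAX_CUES):
            rec[f"cue_loc_{j + 1}"] = tr.cue_locations[j] if j < tr.n_cues else -1
            rec[f"cue_onset_{j + 1}"] = tr.cue_onsets[j] if j < tr.n_cues else -1
        rec["fp_offset"] = tr.fp_offset_time
        rec["stim"] = tr.stimulation.value
        rec["category"] = out.category.value
        rec["chosen_location"] = -1 if out.chosen_location is None else out.chosen_location
        rec["rt_ms"] = np.nan if out.reaction_time is None else out.reaction_time
        ex, ey = (np.nan, np.nan) if out.endpoint is None else out.endpoint
        rec["endpoint_x"], rec["endpoint_y"] = ex, ey
        recs.append(rec)
    return pd.DataFrame(recs)


def outcomes_to_frame(outcomes: Sequence[ChoiceOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [o.category.value for o in outcomes],
            "chosen_location": [
                -1 if o.chosen_location is None else o.chosen_location for o in outcomes
            ],
            "rt_ms": [np.nan if o.reaction_time is None else o.reaction_time for o in outcomes],
        }
    )


def _frame_to_trials(df: pd.DataFrame, config: TaskConfig, hemisphere: str):
    hemimap = config.hemifield_map(hemisphere)
    trials, outcomes = [], []
    for _, row in df.iterrows():
        n = int(row["n_cues"])
        locs = [int(row[f"cue_loc_{j + 1}"]) for j in range(n)]
        onsets = [int(row[f"cue_onset_{j + 1}"]) for j in range(n)]
        trials.append(
            Trial(
                trial_id=int(row["trial_id"]),
                rule=Rule(row["rule"]),
                cue_locations=locs,
                cue_onsets=onsets,
                fp_offset_time=int(row["fp_offset"]),
                stimulation=Stimulation(row["stim"]),
                hemifield_map=dict(hemimap),
            )
        )
        chosen = int(row["chosen_location"])
        rt = row["rt_ms"]
        ex, ey = row["endpoint_x"], row["endpoint_y"]
        outcomes.append(
            ChoiceOutcome(
                chosen_location=None if chosen < 0 else chosen,
                category=ChoiceCategory(row["category"]),
                reaction_time=None if pd.isna(rt) else float(rt),
                endpoint=None if pd.isna(ex) else (float(ex), float(ey)),
            )
        )
    return trials, outcomes


# ---------------------------------------------------------------------------
# directory read/write
# ---------------------------------------------------------------------------

def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle as a session directory (deterministic bytes)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.validate()

    (path / "meta.json").write_text(json.dumps(bundle.meta, indent=2, sort_keys=True) + "\n")
    trials_to_frame(bundle.trials, bundle.outcomes).to_csv(
        path / "trials.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    bundle.spikes.to_csv(
        path / "spikes.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    bundle.neurons.to_csv(
        path / "neurons.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    if bundle.eye is not None:
        pd.DataFrame(bundle.eye, columns=["t_ms", "x_deg", "y_deg"]).to_csv(
            path / "eye.csv", index=False, float_format="%.4f", lineterminator="\n"
        )
    if bundle.truth is not None:
        (path / "truth.json").write_text(
            json.dumps(bundle.truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory."""
    path = Path(path)
    for fname in ("meta.json", "trials.csv", "spikes.csv", "neurons.csv"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing required session file: {fname}")

    meta = json.loads((path / "meta.json").read_text())
    config = TaskConfig.from_dict(meta["task_config"])
    hemisphere = meta.get("recorded_hemisphere", "left")
    if hemisphere not in ("left", "right"):
        raise SessionFormatError(
            f"meta.json: recorded_hemisphere must be 'left' or 'right', got {hemisphere!r}"
        )

    tdf = pd.read_csv(path / "trials.csv")
    required_cols = {"trial_id", "rule", "n_cues", "fp_offset", "stim", "category"}
    missing = required_cols - set(tdf.columns)
    if missing:
        raise SessionFormatError(f"trials.csv missing columns: {sorted(missing)}")
    trials, outcomes = _frame_to_trials(tdf, config, hemisphere)

    spikes = pd.read_csv(path / "spikes.csv")
    if list(spikes.columns) != ["neuron_id", "t_ms"]:
        raise SessionFormatError("spikes.csv must have columns neuron_id,t_ms")
    neurons = pd.read_csv(path / "neurons.csv")
    if "neuron_id" not in neurons.columns:
        raise SessionFormatError("neurons.csv must have a neuron_id column")

    eye = None
    if (path / "eye.csv").exists():
        eye_df = pd.read_csv(path / "eye.csv")
        if list(eye_df.columns) != ["t_ms", "x_deg", "y_deg"]:
            raise SessionFormatError("eye.csv must have columns t_ms,x_deg,y_deg")
        eye = eye_df.to_numpy(dtype=float)
    else:
        warnings.warn(
            "eye.csv not found: behavior stages that need eye traces are unavailable",
            stacklevel=2,
        )

    truth = None
    if (path / "truth.json").exists():
        truth = GroundTruth.from_dict(json.loads((path / "truth.json").read_text()))

    bundle = SessionBundle(
        meta=meta, trials=trials, outcomes=outcomes, spikes=spikes,
        neurons=neurons, eye=eye, truth=truth,
    )
    bundle.validate()
    return bundle
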