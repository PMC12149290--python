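"""Oculomotor n-back task model.

The task: while fixating, a monkey watches 2-4 brief peripheral cues
(150 ms each) separated by 800-ms delays.  At fixation-point (FP) offset it
must saccade to the most recent cue (1-back rule) or to the one-previous cue
(2-back rule).  This module encodes the task geometry and timing, the
trial event schedule, the memory bookkeeping (which locations must currently
be held, and which memory just became obsolete -- the "extinction" event),
and the behavioral outcome taxonomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Rule",
    "Stimulation",
    "ChoiceCategory",
    "TaskConfig",
    "Trial",
    "ChoiceOutcome",
    "DelayEpoch",
    "target_location",
    "required_memory_set",
    "extinction_location",
    "classify_choice",
    "delay_epochs",
    "EPOCH_MS",
]

#: width of the early/late sub-epochs into which each delay is split (ms)
EPOCH_MS = 400


class Rule(str, Enum):
    """Task rule signalled by the fixation point's shape/color."""

    ONE_BACK = "1-back"
    TWO_BACK = "2-back"


class Stimulation(str, Enum):
    """Electrical-stimulation condition of a trial (timing within the last delay)."""

    NONE = "none"
    EARLY_LAST_DELAY = "early"
    LATE_LAST_DELAY = "late"


class ChoiceCategory(str, Enum):
    CORRECT = "correct"
    RULE_ERROR = "rule_error"
    MEM_ERROR_23BACK = "mem_error_23back"
    MEM_ERROR_RANDOM = "mem_error_random"
    FIXATION_BREAK = "fixation_break"
    NO_RESPONSE = "no_response"


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing constants of the oculomotor n-back paradigm.

    All durations are in milliseconds, angles in degrees measured
    counterclockwise from the rightward horizontal, eccentricity in degrees
    of visual angle.  Defaults are the values used in the original
    experiments.
    """

    n_locations: int = 4
    location_angles: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    eccentricity: float = 12.0
    cue_duration: int = 150
    delay_duration: int = 800
    cue_count_range: tuple[int, int] = (2, 4)
    target_reappear_after_fp_off: int = 400
    max_reaction_time: int = 400
    target_window: float = 4.0
    intertrial_interval: int = 800

    def __post_init__(self) -> None:
        if len(self.location_angles) != self.n_locations:
            raise ValueError("location_angles length must equal n_locations")
        wrapped = [a % 360.0 for a in self.location_angles]
        if len(set(wrapped)) != len(wrapped):
            raise ValueError("location_angles must be pairwise distinct mod 360")
        for name in (
            "cue_duration",
            "delay_duration",
            "target_reappear_after_fp_off",
            "max_reaction_time",
            "intertrial_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.cue_count_range
        if not (2 <= lo <= hi <= 4):
            raise ValueError("cue_count_range must lie within [2, 4]")

    # -- geometry helpers ---------------------------------------------------
    def location_xy(self, loc: int) -> tuple[float, float]:
        """Cartesian cue position (deg) of a 0-based location index."""
        a = np.deg2rad(self.location_angles[loc])
        return (self.eccentricity * float(np.cos(a)), self.eccentricity * float(np.sin(a)))

    def hemifield(self, loc: int) -> str:
        """'left', 'right' or 'mid' visual hemifield of a location."""
        x = np.cos(np.deg2rad(self.location_angles[loc]))
        if abs(x) < 1e-9:
            return "mid"
        return "right" if x > 0 else "left"

    def hemifield_map(self, recorded_hemisphere: str) -> dict[int, str]:
        """Map location index -> {'ipsi', 'contra', 'mid'} for a hemisphere.

        Contralateral means the visual hemifield opposite the recorded
        hemisphere (e.g. right hemifield for a left-hemisphere recording).
        """
        if recorded_hemisphere not in ("left", "right"):
            raise ValueError("recorded_hemisphere must be 'left' or 'right'")
        contra = "right" if recorded_hemisphere == "left" else "left"
        out = {}
        for loc in range(self.n_locations):
            h = self.hemifield(loc)
            out[loc] = "mid" if h == "mid" else ("contra" if h == contra else "ipsi")
        return out

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["location_angles"] = list(self.location_angles)
        d["cue_count_range"] = list(self.cue_count_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "location_angles" in d:
            d["location_angles"] = tuple(d["location_angles"])
        if "cue_count_range" in d:
            d["cue_count_range"] = tuple(d["cue_count_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class Trial:
    """One trial: cue sequence, event times (ms, session clock) and condition."""

    trial_id: int
    rule: Rule
    cue_locations: list[int]
    cue_onsets: list[int]
    fp_offset_time: int
    stimulation: Stimulation = Stimulation.NONE
    hemifield_map: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        if len(self.cue_onsets) != len(self.cue_locations):
            raise ValueError("cue_onsets and cue_locations must have equal length")
        if len(self.cue_locations) < 2:
            raise ValueError("a trial needs at least two cues")

    @property
    def n_cues(self) -> int:
        return len(self.cue_locations)

    def delay_start(self, k: int, config: TaskConfig) -> int:
        """Start (ms) of the delay period after cue k (1-based)."""
        return self.cue_onsets[k - 1] + config.cue_duration

    def stim_onset(self, config: TaskConfig) -> Optional[int]:
        """Onset time of electrical stimulation (ms) or None."""
        last_delay_start = self.cue_onsets[-1] + config.cue_duration
        if self.stimulation is Stimulation.EARLY_LAST_DELAY:
            return last_delay_start
        if self.stimulation is Stimulation.LATE_LAST_DELAY:
            return last_delay_start + EPOCH_MS
        return None


@dataclass
class ChoiceOutcome:
    """Classified behavioral result of one trial."""

    chosen_location: Optional[int]
    category: ChoiceCategory
    reaction_time: Optional[float] = None
    endpoint: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class DelayEpoch:
    """One delay period split into its early and late 400-ms epochs."""

    delay_index: int                 # 1-based, after cue k
    early: tuple[int, int]           # [start, start+400) ms
    late: tuple[int, int]            # [start+400, start+800) ms
    tag: Optional[str] = None        # 'D1' (second-to-last) / 'D2' (last)


def target_location(rule: Rule, cue_locations: Sequence[int]) -> int:
    """Saccade goal: last cue under the 1-back rule, second-to-last under 2-back."""
    if len(cue_locations) < 2:
        raise ValueError("invalid trial: cue sequence shorter than 2")
    return cue_locations[-1] if rule is Rule.ONE_BACK else cue_locations[-2]


def required_memory_set(rule: Rule, cue_locations: Sequence[int], k: int) -> set[int]:
    """Locations that must be held in memory during the delay after cue k (1-based).

    Under 1-back only the most recent cue matters; under 2-back the two most
    recent cues do (one location if they coincide).
    """
    if not 1 <= k <= len(cue_locations):
        raise IndexError(f"cue index k={k} out of range 1..{len(cue_locations)}")
    if rule is Rule.ONE_BACK or k == 1:
        return {cue_locations[k - 1]}
    return {cue_locations[k - 2], cue_locations[k - 1]}


def extinction_location(rule: Rule, cue_locations: Sequence[int], k: int) -> Optional[int]:
    """The location whose memory became obsolete at cue k, if any.

    A location "extinguishes" when it was in the required memory set during
    the previous delay but is not after cue k.  Repeats of the same location
    produce no extinction event, and nothing can extinguish at the first cue.
    """
    if not 1 <= k <= len(cue_locations):
        raise IndexError(f"cue index k={k} out of range 1..{len(cue_locations)}")
    if k == 1:
        return None
    dropped = required_memory_set(rule, cue_locations, k - 1) - required_memory_set(
        rule, cue_locations, k
    )
    if not dropped:
        return None
    if len(dropped) > 1:  # cannot occur: sets have size <= 2 and overlap by recency
        raise AssertionError("more than one location extinguished at once")
    return dropped.pop()


def classify_choice(
    rule: Rule, cue_locations: Sequence[int], chosen_location: int
) -> ChoiceCategory:
    """Behavioral error taxonomy for a completed saccade to ``chosen_location``.

    CORRECT: the rule-defined target.  RULE_ERROR: the other of the last two
    cue locations (the wrong rule was applied).  MEM_ERROR_23BACK: an earlier
    cue location within the trial.  MEM_ERROR_RANDOM: a location never cued.
    """
    cues = list(cue_locations)
    if chosen_location is None or chosen_location < 0:
        raise ValueError("chosen_location must be a valid location index")
    target = target_location(rule, cues)
    if chosen_location == target:
        return ChoiceCategory.CORRECT
    other = cues[-1] if rule is Rule.TWO_BACK else cues[-2]
    if chosen_location == other:
        return ChoiceCategory.RULE_ERROR
    if chosen_location in cues:
        return ChoiceCategory.MEM_ERROR_23BACK
    return ChoiceCategory.MEM_ERROR_RANDOM


def delay_epochs(trial: Trial, config: TaskConfig) -> list[DelayEpoch]:
    """Early/late 400-ms epochs of every delay period of a trial.

    The last two delays are tagged 'D1' and 'D2' (the decoding features).
    """
    epochs = []
    n = trial.n_cues
    for k in range(1, n + 1):
        start = trial.cue_onsets[k - 1] + config.cue_duration
        tag = "D2" if k == n else ("D1" if k == n - 1 else None)
        epochs.append(
            DelayEpoch(
                delay_index=k,
                early=(start, start + EPOCH_MS),
                late=(start + EPOCH_MS, start + 2 * EPOCH_MS),
                tag=tag,
            )
        )
    return epochs
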