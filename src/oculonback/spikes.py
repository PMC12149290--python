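"""Spike-train summaries and population statistics.

Spike density functions (Gaussian kernel, sigma = 20 ms), 400-ms epoch spike
counts per delay period, session-wide z-normalization from 100-ms bins, the
task-relatedness screen (epoch vs pre-cue baseline, unpaired t), aligned
population averages (150-ms windows in 10-ms steps, rows sorted by peak
time), sliding-window paired t tests (100-ms windows, 20-ms steps,
uncorrected), and the 2x2 within-subject ANOVA over (stimulus order x task
rule) cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REWARD_AFTER_FP_MS
from .task import EPOCH_MS, TaskConfig, Trial, delay_epochs

__all__ = [
    "spike_density",
    "epoch_counts",
    "ZScorer",
    "zscore_normalize",
    "ScreenResult",
    "task_related_screen",
    "window_counts",
    "population_average",
    "sliding_ttest",
    "rm_anova_2x2",
]

SDF_SIGMA_MS = 20.0
#: screen epochs relative to FP offset / reward; windows are package constants
SCREEN_EPOCHS = ("cue", "delay", "saccade", "reward")


def spike_density(
    timestamps: np.ndarray, t_grid: np.ndarray, sigma: float = SDF_SIGMA_MS
) -> np.ndarray:
    """Spike density function (spikes/s) on a millisecond grid.

    Each spike contributes a Gaussian kernel of width ``sigma`` (ms) with
    unit integral, so the trace integrates to the spike count and a single
    spike peaks at 1/(sigma*sqrt(2*pi)) in per-second units.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty evaluation grid")
    ts = np.sort(np.asarray(timestamps, dtype=float))
    out = np.zeros_like(t_grid)
    if ts.size == 0:
        return out
    half = 6.0 * sigma
    norm = 1000.0 / (sigma * np.sqrt(2.0 * np.pi))   # spikes/s peak per spike
    for t in ts:
        lo = np.searchsorted(t_grid, t - half)
        hi = np.searchsorted(t_grid, t + half)
        if hi > lo:
            d = t_grid[lo:hi] - t
            out[lo:hi] += norm * np.exp(-0.5 * (d / sigma) ** 2)
    return out


def epoch_counts(
    timestamps: np.ndarray, trials: Sequence[Trial], config: TaskConfig
) -> pd.DataFrame:
    """Spike counts in the early/late 400-ms epochs of every delay period.

    Returns one row per (trial, delay, epoch) with alignment metadata
    (epoch start time and the D1/D2 tag on the last two delays).
    """
    ts = np.sort(np.asarray(timestamps, dtype=float))
    recs = []
    for tr in trials:
        for ep in delay_epochs(tr, config):
            for name, (a, b) in (("early", ep.early), ("late", ep.late)):
                n = int(np.searchsorted(ts, b) - np.searchsorted(ts, a))
                recs.append(
                    {
                        "trial_id": tr.trial_id,
                        "delay_index": ep.delay_index,
                        "epoch": name,
                        "tag": ep.tag,
                        "t0": a,
                        "count": n,
                    }
                )
    return pd.DataFrame(recs)


@dataclass
class ZScorer:
    """Per-neuron z-normalization from 100-ms task-time spike-count bins."""

    mu: float          # mean count per 100-ms bin
    sigma: float       # SD of counts per 100-ms bin
    n_bins: int
    ok: bool           # False for silent neurons (zero SD): excluded downstream

    def z(self, counts: np.ndarray, window_ms: float = 100.0) -> np.ndarray:
        """Z-score counts measured in ``window_ms`` windows (scaled to 100 ms)."""
        if not self.ok:
            raise ValueError("z-scoring unavailable: zero-variance (silent) neuron")
        scaled = np.asarray(counts, dtype=float) * (100.0 / window_ms)
        return (scaled - self.mu) / self.sigma


def zscore_normalize(
    timestamps: np.ndarray,
    task_spans: Sequence[tuple[float, float]],
    bin_ms: float = 100.0,
) -> tuple[np.ndarray, ZScorer]:
    """Bin a spike train in 100-ms bins over task time and z-score the bins.

    Returns the z-scored bin series (NaN series when the neuron is silent)
    and the :class:`ZScorer` carrying the (mu, sigma) used.
    """
    ts = np.sort(np.asarray(timestamps, dtype=float))
    counts = []
    for a, b in task_spans:
        edges = np.arange(a, b + 1e-9, bin_ms)
        if len(edges) < 2:
            continue
        c, _ = np.histogram(ts, bins=edges)
        counts.append(c)
    if not counts:
        raise ValueError("no task spans to bin")
    counts = np.concatenate(counts).astype(float)
    mu = float(counts.mean())
    sd = float(counts.std(ddof=0))
    scorer = ZScorer(mu=mu, sigma=sd if sd > 0 else np.nan, n_bins=len(counts), ok=sd > 0)
    zs = (counts - mu) / sd if sd > 0 else np.full_like(counts, np.nan)
    return zs, scorer


@dataclass
class ScreenResult:
    passed: bool
    pvalues: dict[str, float] = field(default_factory=dict)
    excluded_reason: Optional[str] = None


def task_related_screen(
    timestamps: np.ndarray,
    trials: Sequence[Trial],
    config: TaskConfig,
    n_blocks: int = 99,
    min_blocks: int = 5,
    epochs: Sequence[str] = SCREEN_EPOCHS,
    alpha: float = 0.05,
) -> ScreenResult:
    """Screen a neuron for task-related modulation.

    Per-trial 400-ms-equivalent spike counts in the cue-response epoch
    (mean over 0-400 ms after each cue onset), the delay (mean over each
    delay period's early/late 400-ms epochs), the saccade epoch (0-400 ms
    after FP offset) and the reward epoch (0-400 ms after reward time) are
    each compared to the pre-first-cue baseline (400 ms) with an unpaired
    (Welch) t test; the neuron passes if any epoch has p < alpha.  The cue
    epoch mirrors the visual-response criterion used when isolating
    task-related neurons; cue-locked transients would otherwise be
    invisible to the screen.  Neurons
    recorded for fewer than ``min_blocks`` trial blocks are excluded
    outright.
    """
    if n_blocks < min_blocks:
        return ScreenResult(False, excluded_reason=f"recorded < {min_blocks} blocks")
    ts = np.sort(np.asarray(timestamps, dtype=float))

    def window_count(a):
        return np.searchsorted(ts, a + EPOCH_MS) - np.searchsorted(ts, a)

    def delay_mean(tr):
        eps = delay_epochs(tr, config)
        vals = [window_count(ep.early[0]) for ep in eps] + [
            window_count(ep.late[0]) for ep in eps
        ]
        return float(np.mean(vals))

    base = np.array([window_count(tr.cue_onsets[0] - EPOCH_MS) for tr in trials])
    def cue_mean(tr):
        return float(np.mean([window_count(on) for on in tr.cue_onsets]))

    values = {
        "cue": cue_mean,
        "delay": lambda tr: delay_mean(tr),
        "saccade": lambda tr: window_count(tr.fp_offset_time),
        "reward": lambda tr: window_count(tr.fp_offset_time + REWARD_AFTER_FP_MS),
    }
    pvals = {}
    for name in epochs:
        counts = np.array([values[name](tr) for tr in trials], dtype=float)
        if base.std() == 0 and counts.std() == 0:
            pvals[name] = 1.0
            continue
        _, p = stats.ttest_ind(counts, base, equal_var=False)
        pvals[name] = float(p)
    return ScreenResult(passed=any(p < alpha for p in pvals.values()), pvalues=pvals)


# ---------------------------------------------------------------------------
# aligned windows, population averages, sliding tests
# ---------------------------------------------------------------------------

def window_counts(
    timestamps: np.ndarray,
    events: Sequence[float],
    t_range: tuple[float, float],
    width: float = 150.0,
    step: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned sliding-window spike counts.

    Returns (centers, matrix) where ``matrix[i, j]`` is the count in the
    window starting ``t_range[0] + j*step`` after event i; centers are
    window centers relative to the event.  Window-count arithmetic:
    n_windows = floor((span - width)/step) + 1.
    """
    ts = np.sort(np.asarray(timestamps, dtype=float))
    span = t_range[1] - t_range[0]
    n_win = int(np.floor((span - width) / step)) + 1
    if n_win < 1:
        raise ValueError("t_range shorter than one window")
    offsets = t_range[0] + np.arange(n_win) * step
    centers = offsets + width / 2.0
    mat = np.empty((len(events), n_win))
    for i, ev in enumerate(events):
        a = ev + offsets
        mat[i] = np.searchsorted(ts, a + width) - np.searchsorted(ts, a)
    return centers, mat


def population_average(
    traces: Sequence[np.ndarray], baselines: Optional[Sequence[float]] = None
) -> dict:
    """Population heatmap and mean +/- SEM from per-neuron normalized traces.

    ``traces`` are equal-length per-neuron activity vectors (z-scored,
    event-aligned).  Rows are sorted by the time of peak activity.  The
    optional per-neuron baselines (mean z in the 400-ms pre-first-cue
    window) are carried through for plotting a baseline reference.
    """
    if len(traces) == 0:
        raise ValueError("empty neuron set")
    mat = np.vstack(traces)
    order = np.argsort(np.argmax(mat, axis=1), kind="stable")
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(
        mat.shape[1]
    )
    out = {"heatmap": mat[order], "order": order, "mean": mean, "sem": sem}
    if baselines is not None:
        out["baseline"] = float(np.mean(baselines))
    return out


def sliding_ttest(condition_a: np.ndarray, condition_b: np.ndarray) -> np.ndarray:
    """Paired t test per aligned window (no multiple-comparison correction).

    Inputs are (n_units x n_windows) activity matrices for two matched
    conditions (windows typically 100 ms wide in 20-ms steps); returns the
    per-window p-value trace.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    diffs = a - b
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_rel(a, b, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    p[np.all(diffs == 0, axis=0)] = 1.0
    return p


def rm_anova_2x2(cells: np.ndarray) -> dict:
    """2x2 within-subject ANOVA from per-subject cell means.

    ``cells`` has shape (n_subjects, 2, 2) indexed (subject, order, rule).
    With two levels per factor every effect has 1 numerator df and reduces
    to a paired contrast: F equals the squared paired t of the per-subject
    contrast scores, with df (1, n-1).  Subjects with missing cells are
    dropped.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n, 2, 2)")
    keep = ~np.isnan(cells).any(axis=(1, 2))
    cells = cells[keep]
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects with complete cells")
    contrasts = {
        "order": (cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)),
        "rule": (cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1)),
        "interaction": (cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]) / 2.0,
    }
    out: dict[str, dict] = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            t = 0.0 if np.allclose(c.mean(), 0) else np.inf
        else:
            t = c.mean() / (sd / np.sqrt(n))
        F = float(t**2)
        p = float(stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = {"F": F, "p": p, "df": (1, n - 1)}
    out["n"] = n
    return out
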