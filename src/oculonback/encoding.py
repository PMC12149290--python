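"""Poisson encoding model of delay-period activity and neuron classification.

Each delay period contributes two observations: the spike count in its early
400 ms, modelled from Visual, Extinction, Order and Rule covariates, and the
count in its late 400 ms, modelled from Memory, Order and Rule covariates::

    log E[SPK_early] = b_v . Visual + b_e . Extinction + b_o*Order + b_r*Rule + bias
    log E[SPK_late]  = b_m . Memory                    + b_o*Order + b_r*Rule + bias

Visual, Extinction and Memory are 4-long location dummies (e.g. a cue in the
upper-right location codes Visual = [1 0 0 0]; a lower-left memory becoming
obsolete codes Extinction = [0 0 1 0]).  Order is the serial cue position
scaled to [0, 1]; Rule is 0/1 for 1-back/2-back.  Stacking the two epoch
models (with separate Order, Rule and bias terms each) gives 18
coefficients, fitted jointly by a log-link Poisson GLM on spike counts
scaled to 0-100 % of the neuron's maximum epoch count.

A neuron carries a component when any of that component's coefficients
differs from zero (Wald p < 0.05); the directionality of the Visual,
Extinction and Memory components is the vector sum of their four location
betas, with directional index DI = |sum_i b_i u_i| / sum_i |b_i| and
preferred direction the angle of the summed vector.  DI > 0.1 defines a
directional neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spikes import epoch_counts, task_related_screen
from .task import (
    ChoiceCategory,
    ChoiceOutcome,
    Rule,
    TaskConfig,
    Trial,
    extinction_location,
    required_memory_set,
)
from .simulate import order_scalar

__all__ = [
    "DESIGN_COLUMNS",
    "poisson_deviance",
    "COMPONENT_COLUMNS",
    "build_design",
    "ComponentFit",
    "fit_poisson_glm",
    "directional_index",
    "DirectionalSummary",
    "NeuronLabels",
    "classify_neuron",
    "EncodingModel",
    "EncodingResults",
    "fit_session",
]

DESIGN_COLUMNS = (
    ["vis_0", "vis_1", "vis_2", "vis_3"]
    + ["ext_0", "ext_1", "ext_2", "ext_3"]
    + ["mem_0", "mem_1", "mem_2", "mem_3"]
    + ["order_early", "rule_early", "bias_early"]
    + ["order_late", "rule_late", "bias_late"]
)

COMPONENT_COLUMNS = {
    "visual": ["vis_0", "vis_1", "vis_2", "vis_3"],
    "extinction": ["ext_0", "ext_1", "ext_2", "ext_3"],
    "memory": ["mem_0", "mem_1", "mem_2", "mem_3"],
    "order": ["order_early", "order_late"],
    "rule": ["rule_early", "rule_late"],
}

DIRECTIONAL_COMPONENTS = ("visual", "extinction", "memory")
DI_THRESHOLD = 0.1
ALPHA = 0.05

_COMPLETED = (
    ChoiceCategory.CORRECT,
    ChoiceCategory.RULE_ERROR,
    ChoiceCategory.MEM_ERROR_23BACK,
    ChoiceCategory.MEM_ERROR_RANDOM,
)


def build_design(
    trials: Sequence[Trial],
    counts: pd.DataFrame,
    outcomes: Optional[Sequence[ChoiceOutcome]] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack the per-delay design rows and the response vector.

    ``counts`` is the epoch-count table from :func:`~oculonback.spikes.epoch_counts`
    for one neuron.  Each delay period yields exactly two rows (early, late).
    Trials whose behavioral outcome is not classifiable (fixation break,
    no response) are excluded when ``outcomes`` is supplied.  The response
    is the raw spike count; scaling is the model's concern.
    """
    keep = {}
    for i, tr in enumerate(trials):
        if outcomes is not None and outcomes[i].category not in _COMPLETED:
            continue
        keep[tr.trial_id] = tr

    by_key = {
        (int(r.trial_id), int(r.delay_index), r.epoch): int(r.count)
        for r in counts.itertuples()
    }
    rows, y = [], []
    for tid, tr in keep.items():
        rule01 = 1.0 if tr.rule is Rule.TWO_BACK else 0.0
        for k in range(1, tr.n_cues + 1):
            row_e = dict.fromkeys(DESIGN_COLUMNS, 0.0)
            row_e[f"vis_{tr.cue_locations[k - 1]}"] = 1.0
            ext = extinction_location(tr.rule, tr.cue_locations, k)
            if ext is not None:
                row_e[f"ext_{ext}"] = 1.0
            row_e["order_early"] = order_scalar(k)
            row_e["rule_early"] = rule01
            row_e["bias_early"] = 1.0

            row_l = dict.fromkeys(DESIGN_COLUMNS, 0.0)
            for loc in required_memory_set(tr.rule, tr.cue_locations, k):
                row_l[f"mem_{loc}"] = 1.0
            row_l["order_late"] = order_scalar(k)
            row_l["rule_late"] = rule01
            row_l["bias_late"] = 1.0

            rows.extend((row_e, row_l))
            y.append(by_key.get((tid, k, "early"), 0))
            y.append(by_key.get((tid, k, "late"), 0))
    X = pd.DataFrame(rows, columns=DESIGN_COLUMNS, dtype=float)
    return X, np.asarray(y, dtype=float)


@dataclass
class ComponentFit:
    """The 18-coefficient fit of one neuron's encoding model."""

    params: pd.Series          # indexed by DESIGN_COLUMNS; NaN for dropped columns
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    flagged: bool              # non-convergence or separation
    deviance_history: list[float]
    n_obs: int
    dropped: list[str]

    def significant_components(self, alpha: float = ALPHA) -> set[str]:
        out = set()
        for comp, cols in COMPONENT_COLUMNS.items():
            ps = self.pvalues[cols].dropna()
            if len(ps) and (ps < alpha).any():
                out.add(comp)
        return out


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance, valid for non-negative (possibly scaled) responses."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _sum_zero_basis(k: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^k (k x (k-1))."""
    q, _ = np.linalg.qr(np.eye(k) - np.full((k, k), 1.0 / k))
    return q[:, : k - 1]


def _constraint_map(columns: Sequence[str]) -> np.ndarray:
    """Map reduced parameters to the full column set.

    The four visual dummies sum to the early bias column on every early row
    (exactly one cue precedes each delay), so the visual block is identified
    by a sum-to-zero constraint: its betas are contrasts of early-epoch rate
    across cue locations.  All other columns map one-to-one.
    """
    vis = [i for i, c in enumerate(columns) if c.startswith("vis_")]
    others = [i for i, c in enumerate(columns) if not c.startswith("vis_")]
    n_red = len(others) + max(0, len(vis) - 1)
    T = np.zeros((len(columns), n_red))
    j = 0
    if len(vis) > 1:
        T[np.ix_(vis, range(len(vis) - 1))] = _sum_zero_basis(len(vis))
        j = len(vis) - 1
    for i in others:
        T[i, j] = 1.0
        j += 1
    return T


def _irls(X, y, maxiter=100, tol=1e-8):
    """Damped IRLS for the Poisson log-link model.

    Step-halving makes the deviance non-increasing across iterations;
    singular weighted systems are solved in the minimum-norm sense.
    """
    start = np.log(np.clip(y, 0.2, None) + 0.3)
    beta, *_ = np.linalg.lstsq(X, start, rcond=None)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    dev = poisson_deviance(y, mu)
    history = [dev]
    converged = False
    for _ in range(maxiter):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        target, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        step = target - beta
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            mu_c = np.exp(np.clip(X @ cand, -30.0, 30.0))
            dev_c = poisson_deviance(y, mu_c)
            if dev_c <= dev + 1e-10:
                break
            t *= 0.5
        else:
            converged = True          # no descent direction left: at optimum
            break
        beta = beta + t * step
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        history.append(dev_c)
        if abs(dev - dev_c) < tol * (abs(dev_c) + 0.1):
            dev = dev_c
            converged = True
            break
        dev = dev_c
    cov = np.linalg.pinv((X * mu[:, None]).T @ X)
    return beta, cov, history, converged


def fit_poisson_glm(
    design: pd.DataFrame, response: np.ndarray, maxiter: int = 100
) -> ComponentFit:
    """Fit the log-link Poisson GLM by damped IRLS.

    All-zero columns are dropped before fitting and reported as absent
    (NaN), not zero; the visual block carries a sum-to-zero identification
    constraint (see :func:`_constraint_map`).  Wald SEs and p-values use
    the observed information without dispersion correction.  Non-convergence
    within ``maxiter`` iterations or diverging coefficients flag the fit.
    """
    nz = [c for c in design.columns if np.any(design[c].to_numpy() != 0.0)]
    dropped = [c for c in design.columns if c not in nz]
    X = design[nz].to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("design and response lengths differ")
    if np.any(y < 0):
        raise ValueError("negative response counts")

    T = _constraint_map(nz)
    gamma, cov_g, history, converged = _irls(X @ T, y, maxiter=maxiter)
    beta = T @ gamma
    cov = T @ cov_g @ T.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.where(se > 0, pvals, 1.0)

    flagged = (not converged) or bool(np.any(np.abs(beta) > 20))

    def expand(values):
        s = pd.Series(np.nan, index=design.columns, dtype=float)
        s[nz] = np.asarray(values, dtype=float)
        return s

    return ComponentFit(
        params=expand(beta),
        bse=expand(se),
        pvalues=expand(pvals),
        converged=converged,
        flagged=flagged,
        deviance_history=[float(d) for d in history],
        n_obs=len(y),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# directionality and classification
# ---------------------------------------------------------------------------

@dataclass
class DirectionalSummary:
    component: str
    di: float
    preferred_angle: Optional[float]    # deg, None when the beta vector is null
    directional: bool                   # DI > 0.1
    contra: Optional[bool] = None


def directional_index(
    betas: Sequence[float], location_angles: Sequence[float], norm: str = "l1"
) -> tuple[float, Optional[float]]:
    """Directional index and preferred direction from four location betas.

    The summed vector is v = sum_i beta_i * (cos a_i, sin a_i); DI is
    |v| normalised by sum|beta| (``norm='l1'``, default) or by 4*max|beta|
    (``norm='max'``); missing (absent) betas contribute zero.
    """
    b = np.asarray(betas, dtype=float)
    b = np.where(np.isnan(b), 0.0, b)
    a = np.deg2rad(np.asarray(location_angles, dtype=float))
    v = np.array([np.sum(b * np.cos(a)), np.sum(b * np.sin(a))])
    if norm == "l1":
        denom = np.sum(np.abs(b))
    elif norm == "max":
        denom = 4.0 * np.max(np.abs(b)) if len(b) else 0.0
    else:
        raise ValueError("norm must be 'l1' or 'max'")
    if denom == 0:
        return 0.0, None
    di = float(np.hypot(*v) / denom)
    angle = float(np.rad2deg(np.arctan2(v[1], v[0])) % 360.0) if np.hypot(*v) > 0 else None
    return di, angle


def _is_contra(angle_deg: float, hemisphere: str) -> bool:
    """Is a preferred direction in the hemifield opposite the recorded side?"""
    x = np.cos(np.deg2rad(angle_deg))
    return x > 0 if hemisphere == "left" else x < 0


@dataclass
class NeuronLabels:
    """Component labels of one neuron."""

    significant: set[str] = field(default_factory=set)
    directional: set[str] = field(default_factory=set)       # among visual/extinction/memory
    exclusive: Optional[str] = None      # exactly-one-directional-property label
    summaries: dict[str, DirectionalSummary] = field(default_factory=dict)
    preferred_location: dict[str, int] = field(default_factory=dict)
    unclassified: bool = False


def classify_neuron(
    fit: ComponentFit,
    location_angles: Sequence[float],
    hemisphere: str,
    alpha: float = ALPHA,
    di_threshold: float = DI_THRESHOLD,
    norm: str = "l1",
) -> NeuronLabels:
    """Assign component/directional labels from a fitted encoding model.

    A neuron carries a component if any of its betas is significant; it is
    *directional* for visual/extinction/memory if additionally DI > 0.1.
    Neurons with exactly one directional component get the exclusive label
    used for single-property population plots.  Flagged fits are left
    unclassified.
    """
    if fit.flagged:
        return NeuronLabels(unclassified=True)
    labels = NeuronLabels(significant=fit.significant_components(alpha))
    angles = list(location_angles)
    for comp in DIRECTIONAL_COMPONENTS:
        betas = fit.params[COMPONENT_COLUMNS[comp]].to_numpy()
        di, pref = directional_index(betas, angles, norm=norm)
        directional = comp in labels.significant and di > di_threshold and pref is not None
        contra = _is_contra(pref, hemisphere) if pref is not None else None
        labels.summaries[comp] = DirectionalSummary(comp, di, pref, directional, contra)
        if directional:
            labels.directional.add(comp)
            diffs = [abs((pref - a + 180) % 360 - 180) for a in angles]
            labels.preferred_location[comp] = int(np.argmin(diffs))
    if len(labels.directional) == 1:
        labels.exclusive = next(iter(labels.directional))
    return labels


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class EncodingModel:
    """Encoding model of one neuron's delay-period spike counts.

    Parameters
    ----------
    design, counts
        The stacked design matrix (18 columns) and per-row spike counts.
    scale
        ``"percent"`` (default) rescales counts to 0-100 % of the neuron's
        maximum epoch count before fitting, making coefficients comparable
        across neurons; ``"raw"`` fits the counts directly.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        counts: np.ndarray,
        config: Optional[TaskConfig] = None,
        neuron_id: Optional[int] = None,
        scale: str = "percent",
    ):
        if list(design.columns) != DESIGN_COLUMNS:
            raise ValueError("design must have the 18 canonical columns")
        if scale not in ("percent", "raw"):
            raise ValueError("scale must be 'percent' or 'raw'")
        self.design = design.reset_index(drop=True)
        self.counts = np.asarray(counts, dtype=float)
        self.config = config or TaskConfig()
        self.neuron_id = neuron_id
        self.scale = scale

    @classmethod
    def from_session(cls, bundle, neuron_id: int, scale: str = "percent") -> "EncodingModel":
        """Build the model for one neuron of a session bundle."""
        config = bundle.task_config
        ts = bundle.spike_times(neuron_id)
        counts = epoch_counts(ts, bundle.trials, config)
        X, y = build_design(bundle.trials, counts, bundle.outcomes)
        return cls(X, y, config=config, neuron_id=neuron_id, scale=scale)

    @property
    def endog(self) -> np.ndarray:
        if self.scale == "raw":
            return self.counts
        m = self.counts.max()
        return self.counts * (100.0 / m) if m > 0 else self.counts

    def fit(self, maxiter: int = 300) -> "EncodingResults":
        fit = fit_poisson_glm(self.design, self.endog, maxiter=maxiter)
        return EncodingResults(self, fit)


class EncodingResults:
    """Fitted encoding model: coefficients, uncertainty and labels."""

    def __init__(self, model: EncodingModel, fit: ComponentFit):
        self.model = model
        self.fit = fit

    params = property(lambda self: self.fit.params)
    bse = property(lambda self: self.fit.bse)
    pvalues = property(lambda self: self.fit.pvalues)
    converged = property(lambda self: self.fit.converged)
    flagged = property(lambda self: self.fit.flagged)

    def significant_components(self, alpha: float = ALPHA) -> set[str]:
        return self.fit.significant_components(alpha)

    def directional_summary(self, component: str, norm: str = "l1") -> DirectionalSummary:
        if component not in DIRECTIONAL_COMPONENTS:
            raise ValueError(f"no directionality for component {component!r}")
        betas = self.fit.params[COMPONENT_COLUMNS[component]].to_numpy()
        di, pref = directional_index(betas, self.model.config.location_angles, norm=norm)
        return DirectionalSummary(component, di, pref, di > DI_THRESHOLD, None)

    def classify(self, hemisphere: str, **kw) -> NeuronLabels:
        return classify_neuron(
            self.fit, self.model.config.location_angles, hemisphere, **kw
        )

    def summary(self) -> str:
        lines = [
            f"Encoding model (Poisson GLM, log link) -- neuron {self.model.neuron_id}",
            f"n_obs={self.fit.n_obs}  scale={self.model.scale}  "
            f"converged={self.fit.converged}  flagged={self.fit.flagged}",
            f"{'term':<12}{'beta':>10}{'se':>10}{'p':>12}",
        ]
        for name in DESIGN_COLUMNS:
            b, s, p = self.fit.params[name], self.fit.bse[name], self.fit.pvalues[name]
            if np.isnan(b):
                lines.append(f"{name:<12}{'--':>10}{'--':>10}{'--':>12}")
            else:
                lines.append(f"{name:<12}{b:>10.4f}{s:>10.4f}{p:>12.3g}")
        sig = ", ".join(sorted(self.significant_components())) or "none"
        lines.append(f"significant components: {sig}")
        return "\n".join(lines)


def fit_session(
    bundle,
    scale: str = "percent",
    min_blocks: int = 5,
    screen: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Fit and classify every neuron of a session; one row per neuron.

    Neurons recorded for fewer than ``min_blocks`` trial blocks or failing
    the task-relatedness screen are excluded before fitting (their rows
    carry ``included=False``).
    """
    config = bundle.task_config
    hemisphere = bundle.recorded_hemisphere
    n_blocks = dict(zip(bundle.neurons["neuron_id"], bundle.neurons.get(
        "n_blocks", pd.Series([99] * len(bundle.neurons)))))
    rows = []
    for nid in bundle.neuron_ids:
        ts = bundle.spike_times(nid)
        row: dict = {"neuron_id": nid, "included": True, "exclusion": ""}
        scr = task_related_screen(
            ts, bundle.trials, config, n_blocks=int(n_blocks.get(nid, 99)),
            min_blocks=min_blocks,
        ) if screen else None
        if screen and not scr.passed:
            row["included"] = False
            row["exclusion"] = scr.excluded_reason or "task-relatedness screen"
            rows.append(row)
            continue
        res = EncodingModel.from_session(bundle, nid, scale=scale).fit()
        labels = res.classify(hemisphere, alpha=alpha)
        for name in DESIGN_COLUMNS:
            row[f"beta_{name}"] = res.params[name]
            row[f"se_{name}"] = res.bse[name]
            row[f"p_{name}"] = res.pvalues[name]
        row["converged"] = res.converged
        row["flagged"] = res.flagged
        for comp in DIRECTIONAL_COMPONENTS:
            s = labels.summaries.get(comp)
            row[f"di_{comp}"] = s.di if s else np.nan
            row[f"pref_angle_{comp}"] = s.preferred_angle if s else np.nan
            row[f"directional_{comp}"] = comp in labels.directional
            row[f"contra_{comp}"] = bool(s.contra) if s and s.contra is not None else False
            row[f"pref_loc_{comp}"] = labels.preferred_location.get(comp, -1)
        row["significant"] = ",".join(sorted(labels.significant))
        row["exclusive"] = labels.exclusive or ""
        rows.append(row)
    return pd.DataFrame(rows)
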