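"""Pseudo-population decoding of the task rule from delay activity.

Neurons recorded in separate sessions are combined into a pseudo-population:
for every classifier instance, trials are drawn independently per neuron
within each rule, so only rule information that is consistent across the
population survives.  Features are the spike counts in the early and late
400-ms epochs of the last two delay periods (D1, D2) of correct trials in
which the second-to-last cue appeared at the neuron's preferred location
and the last cue elsewhere (P-N-FP-off trials).

The classifier is a linear soft-margin SVM trained on eight randomly chosen
trials per rule (4 epochs x 8 trials x 2 rules = 64 training data points
per neuron); accuracy is measured on 100 validation draws from the held-out
trials, and the training draw is itself repeated 100 times to give an
accuracy distribution.  Variants restrict the feature epochs, exclude one
neuron type at a fixed population size, or validate on rule-error trials to
yield a choice probability (fraction of draws decoding the rule consistent
with the animal's actual choice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .spikes import epoch_counts
from .task import ChoiceCategory, Rule, TaskConfig, Trial

__all__ = [
    "EPOCH_NAMES",
    "NeuronPool",
    "FeatureTensor",
    "build_neuron_pool",
    "build_error_pool",
    "assemble_pseudopopulation",
    "RuleDecoder",
    "DecodeResult",
]

EPOCH_NAMES = ("D1_early", "D1_late", "D2_early", "D2_late")
MIN_TRIALS_PER_RULE = 9          # 8 training + at least 1 validation
N_TRAIN = 8
N_VALIDATION = 100
N_REPEATS = 100
SVM_C = 1.0


@dataclass
class NeuronPool:
    """One neuron's qualifying-trial feature pool, split by rule."""

    neuron_id: int
    features: dict[Rule, np.ndarray]            # (n_trials, 4) epoch counts
    provenance: dict[Rule, list] = field(default_factory=dict)
    session_id: str = ""

    def n_trials(self, rule: Rule) -> int:
        return len(self.features[rule])


def _d1d2_features(ts: np.ndarray, trials: Sequence[Trial], config: TaskConfig):
    """Per-trial 4-epoch count vectors (early/late of D1 and D2)."""
    counts = epoch_counts(ts, trials, config)
    feats = {}
    for tid, g in counts.groupby("trial_id"):
        d1 = g[g["tag"] == "D1"].set_index("epoch")["count"]
        d2 = g[g["tag"] == "D2"].set_index("epoch")["count"]
        feats[tid] = np.array(
            [d1["early"], d1["late"], d2["early"], d2["late"]], dtype=float
        )
    return feats


def build_neuron_pool(
    bundle,
    neuron_id: int,
    preferred_location: int,
    pn_order: str = "P-N",
) -> NeuronPool:
    """Assemble one neuron's P-N-FP-off trial pool from a session.

    ``pn_order='P-N'`` (default, matching the preferred-then-non-preferred
    alignment) requires the second-to-last cue at the preferred location and
    the last cue elsewhere; ``'N-P'`` is the opposite reading.
    """
    if pn_order not in ("P-N", "N-P"):
        raise ValueError("pn_order must be 'P-N' or 'N-P'")
    config = bundle.task_config
    qualifying = []
    for tr, out in zip(bundle.trials, bundle.outcomes):
        if out.category is not ChoiceCategory.CORRECT:
            continue
        prev, last = tr.cue_locations[-2], tr.cue_locations[-1]
        if pn_order == "P-N":
            ok = prev == preferred_location and last != preferred_location
        else:
            ok = last == preferred_location and prev != preferred_location
        if ok:
            qualifying.append(tr)
    feats = _d1d2_features(bundle.spike_times(neuron_id), qualifying, config)
    features, prov = {}, {}
    for rule in Rule:
        tids = [tr.trial_id for tr in qualifying if tr.rule is rule]
        features[rule] = (
            np.vstack([feats[t] for t in tids]) if tids else np.empty((0, 4))
        )
        prov[rule] = tids
    return NeuronPool(
        neuron_id=neuron_id,
        features=features,
        provenance=prov,
        session_id=str(bundle.meta.get("session_id", "")),
    )


def build_error_pool(bundle, neuron_id: int) -> dict:
    """Correct and rule-error trial features for the error-trial analysis.

    Returns ``{"correct": {rule: (n,4)}, "error": {rule: (n,4)}}`` over all
    completed trials (error trials are too scarce to restrict further).
    """
    config = bundle.task_config
    sel = [
        (tr, out)
        for tr, out in zip(bundle.trials, bundle.outcomes)
        if out.category in (ChoiceCategory.CORRECT, ChoiceCategory.RULE_ERROR)
    ]
    feats = _d1d2_features(
        bundle.spike_times(neuron_id), [tr for tr, _ in sel], config
    )
    out: dict = {"correct": {}, "error": {}}
    for rule in Rule:
        for kind, cat in (("correct", ChoiceCategory.CORRECT),
                          ("error", ChoiceCategory.RULE_ERROR)):
            tids = [tr.trial_id for tr, o in sel if tr.rule is rule and o.category is cat]
            out[kind][rule] = (
                np.vstack([feats[t] for t in tids]) if tids else np.empty((0, 4))
            )
    return out


def assemble_pseudopopulation(
    pools: Sequence[NeuronPool], min_trials: int = MIN_TRIALS_PER_RULE
) -> "FeatureTensor":
    """Filter neuron pools to those with enough qualifying trials per rule."""
    kept, excluded = [], []
    for p in pools:
        ns = {rule: p.n_trials(rule) for rule in Rule}
        if all(n >= min_trials for n in ns.values()):
            kept.append(p)
        else:
            excluded.append((p.neuron_id, f"only {min(ns.values())} trials in a rule"))
    return FeatureTensor(pools=kept, excluded=excluded)


@dataclass
class FeatureTensor:
    """The pseudo-population: per-neuron trial pools ready for decoding."""

    pools: list[NeuronPool]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return len(self.pools)

    @property
    def neuron_ids(self) -> list[int]:
        return [p.neuron_id for p in self.pools]


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

_RULES = (Rule.ONE_BACK, Rule.TWO_BACK)   # class labels 0, 1


def _split_pool(rng, features: np.ndarray, n_train: int):
    """Disjoint train/held-out partition of one neuron's rule pool."""
    perm = rng.permutation(len(features))
    return features[perm[:n_train]], features[perm[n_train:]]


def _assemble_instance(rng, pools, epochs, n_train):
    """Training matrix, labels and held-out pools for one classifier instance.

    Pseudo-trial j under rule r concatenates each neuron's j-th sampled
    trial (restricted to the requested epochs); held-out trials are the
    complement of each neuron's training sample, so no validation draw can
    reuse a training trial.
    """
    cols = list(epochs)
    train_rows, held = [], []
    for p in pools:
        per_rule_train, per_rule_held = [], []
        for rule in _RULES:
            tr, hd = _split_pool(rng, p.features[rule], n_train)
            per_rule_train.append(tr)
            per_rule_held.append(hd)
        train_rows.append(per_rule_train)
        held.append(per_rule_held)
    X_train = np.vstack(
        [
            np.hstack([train_rows[i][ri][j][cols] for i in range(len(pools))])
            for ri in range(2)
            for j in range(n_train)
        ]
    )
    y_train = np.repeat([0, 1], n_train)
    return X_train, y_train, held


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


class RuleDecoder:
    """Resampled linear-SVM decoding of the task rule from a pseudo-population.

    All randomness flows from the seed handed to each method; results are
    reproducible bit-for-bit.
    """

    def __init__(self, tensor: FeatureTensor, C: float = SVM_C):
        if tensor.n_neurons == 0:
            raise ValueError("empty pseudo-population")
        self.tensor = tensor
        self.C = C

    # -- core resampling protocol ------------------------------------------
    def accuracy_distribution(
        self,
        n_neurons: int,
        seed: int,
        epochs: Sequence[int] = (0, 1, 2, 3),
        n_train: int = N_TRAIN,
        n_validation: int = N_VALIDATION,
        n_repeats: int = N_REPEATS,
        shuffle_labels: bool = False,
        neuron_subset: Optional[Sequence[int]] = None,
    ) -> np.ndarray:
        """Accuracy of ``n_repeats`` training re-draws at a population size.

        Each repeat samples ``n_neurons`` neurons, then per neuron and rule
        ``n_train`` training trials; a linear SVM (C=1, features
        standardized with training statistics) is evaluated on
        ``n_validation`` pseudo-trials drawn from the held-out trials.
        Validation never reuses a trial in that instance's training set.
        """
        epochs = tuple(epochs)
        if len(epochs) == 0:
            raise ValueError("epochs must not be empty")
        pool_idx = (
            np.arange(self.tensor.n_neurons)
            if neuron_subset is None
            else np.asarray(list(neuron_subset), dtype=int)
        )
        if n_neurons > len(pool_idx):
            raise ValueError(
                f"n_neurons={n_neurons} exceeds available pool ({len(pool_idx)})"
            )
        rng = np.random.default_rng(seed)
        accs = np.empty(n_repeats)
        for r in range(n_repeats):
            chosen = rng.choice(pool_idx, size=n_neurons, replace=False)
            accs[r] = self._one_instance(
                rng, chosen, epochs, n_train, n_validation, shuffle_labels
            )
        return accs

    def training_design(
        self,
        seed: int,
        n_neurons: Optional[int] = None,
        epochs: Sequence[int] = (0, 1, 2, 3),
        n_train: int = N_TRAIN,
    ) -> tuple[np.ndarray, np.ndarray]:
        """One classifier instance's training matrix and labels.

        Rows are the 2 x ``n_train`` pseudo-trials; columns the selected
        epochs of every neuron, so each neuron contributes
        ``len(epochs) * n_train * 2`` training data points.
        """
        rng = np.random.default_rng(seed)
        n = n_neurons or self.tensor.n_neurons
        chosen = rng.choice(self.tensor.n_neurons, size=n, replace=False)
        pools = [self.tensor.pools[i] for i in chosen]
        X, y, _ = _assemble_instance(rng, pools, tuple(epochs), n_train)
        return X, y

    def _one_instance(self, rng, chosen, epochs, n_train, n_validation, shuffle):
        pools = [self.tensor.pools[i] for i in chosen]
        X_train, y_train, held = _assemble_instance(rng, pools, epochs, n_train)
        if shuffle:
            y_train = rng.permutation(y_train)

        X_val, y_val = [], []
        for v in range(n_validation):
            ri = v % 2
            row = []
            for i in range(len(pools)):
                pool = held[i][ri]
                row.append(pool[rng.integers(len(pool))][list(epochs)])
            X_val.append(np.hstack(row))
            y_val.append(ri)
        X_val = np.vstack(X_val)
        y_val = np.asarray(y_val)

        Xt, Xv = _standardize(X_train, X_val)
        clf = SVC(kernel="linear", C=self.C)
        clf.fit(Xt, y_train)
        d = clf.decision_function(Xv)
        pred = np.where(d > 0, clf.classes_[1], clf.classes_[0])  # tie -> 1-back
        return float(np.mean(pred == y_val))

    # -- protocol variants --------------------------------------------------
    def accuracy_curve(
        self, n_neurons_list: Sequence[int], seed: int, **kw
    ) -> pd.DataFrame:
        """Mean +/- SEM accuracy as a function of population size."""
        rows = []
        ss = np.random.SeedSequence(seed).spawn(len(n_neurons_list))
        for n, s in zip(n_neurons_list, ss):
            accs = self.accuracy_distribution(n, seed=s, **kw)
            rows.append(
                {
                    "n_neurons": n,
                    "accuracy_mean": accs.mean(),
                    "accuracy_sem": accs.std(ddof=1) / np.sqrt(len(accs)),
                }
            )
        return pd.DataFrame(rows)

    def epoch_subset_variant(
        self, epochs: Sequence[int], n_neurons: int, seed: int, **kw
    ) -> np.ndarray:
        """Same protocol with features restricted to the requested epochs."""
        return self.accuracy_distribution(n_neurons, seed=seed, epochs=epochs, **kw)

    def type_exclusion_deltas(
        self,
        type_labels: dict[str, set[int]],
        n_fixed: int = 67,
        seed: int = 0,
        n_repeats: int = N_REPEATS,
        **kw,
    ) -> pd.DataFrame:
        """Accuracy change from excluding each neuron type at fixed size.

        ``type_labels`` maps a type name to the neuron ids of that type.
        Delta = mean accuracy with neurons drawn from the full pool minus
        accuracy drawn from the pool without that type; a two-sample t test
        across the training re-draws accompanies each delta.
        """
        ids = self.tensor.neuron_ids
        ss = np.random.SeedSequence(seed).spawn(len(type_labels) + 1)
        full = self.accuracy_distribution(n_fixed, seed=ss[0], n_repeats=n_repeats, **kw)
        rows = []
        for (tname, members), s in zip(type_labels.items(), ss[1:]):
            subset = [i for i, nid in enumerate(ids) if nid not in members]
            if len(subset) < n_fixed:
                rows.append(
                    {"type": tname, "delta": np.nan, "t": np.nan, "p": np.nan,
                     "n_remaining": len(subset)}
                )
                continue
            excl = self.accuracy_distribution(
                n_fixed, seed=s, n_repeats=n_repeats, neuron_subset=subset, **kw
            )
            t, p = stats.ttest_ind(full, excl)
            rows.append(
                {
                    "type": tname,
                    "acc_full": full.mean(),
                    "acc_excluded": excl.mean(),
                    "delta": float(full.mean() - excl.mean()),
                    "t": float(t),
                    "p": float(p),
                    "n_remaining": len(subset),
                }
            )
        return pd.DataFrame(rows)

    # -- error-trial choice probability -------------------------------------
    @staticmethod
    def error_trial_choice_probability(
        error_pools: Sequence[dict],
        seed: int = 0,
        n_train: int = 10,
        n_repeats: int = N_REPEATS,
        n_validation: int = 20,
        C: float = SVM_C,
    ) -> pd.DataFrame:
        """Choice probability of a correct-trial-trained decoder.

        ``error_pools`` holds per-neuron ``{"correct": {rule: (n,4)},
        "error": {rule: (n,4)}}`` features; neurons lacking rule-error
        trials in either rule are dropped.  The decoder is trained on
        ``n_train`` correct trials per rule (100 re-draws); validation on a
        correct trial scores the true rule, validation on a rule-error
        trial scores the rule consistent with the animal's actual choice
        (the opposite of the nominal rule).  Computed for the all-4-epoch
        and first-3-epoch feature sets.  The limited error pools are reused
        across draws; variability comes from the training re-draws.
        """
        pools = [
            p
            for p in error_pools
            if all(len(p["error"][r]) > 0 for r in _RULES)
            and all(len(p["correct"][r]) > n_train for r in _RULES)
        ]
        if not pools:
            return pd.DataFrame()
        rng = np.random.default_rng(seed)
        conditions = [(r, kind) for r in _RULES for kind in ("correct", "error")]
        records: dict = {
            (r.value, kind, es): [] for r, kind in conditions for es in ("all4", "first3")
        }
        epoch_sets = {"all4": (0, 1, 2, 3), "first3": (0, 1, 2)}
        for _ in range(n_repeats):
            train_rows, held = [], []
            for p in pools:
                tr_per_rule, held_per_rule = [], []
                for rule in _RULES:
                    n = len(p["correct"][rule])
                    perm = rng.permutation(n)
                    tr_per_rule.append(p["correct"][rule][perm[:n_train]])
                    held_per_rule.append(p["correct"][rule][perm[n_train:]])
                train_rows.append(tr_per_rule)
                held.append(held_per_rule)
            for es_name, epochs in epoch_sets.items():
                cols = list(epochs)
                X_train = np.vstack(
                    [
                        np.hstack([train_rows[i][ri][j][cols] for i in range(len(pools))])
                        for ri in range(2)
                        for j in range(n_train)
                    ]
                )
                y_train = np.repeat([0, 1], n_train)
                Xt, _ = _standardize(X_train, X_train)
                mu = X_train.mean(axis=0)
                sd = np.where(X_train.std(axis=0) < 1e-12, 1.0, X_train.std(axis=0))
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xt, y_train)
                for ri, rule in enumerate(_RULES):
                    for kind in ("correct", "error"):
                        X_val = []
                        for _v in range(n_validation):
                            row = []
                            for i, p in enumerate(pools):
                                pool = (
                                    held[i][ri] if kind == "correct" else p["error"][rule]
                                )
                                row.append(pool[rng.integers(len(pool))][cols])
                            X_val.append(np.hstack(row))
                        Xv = (np.vstack(X_val) - mu) / sd
                        d = clf.decision_function(Xv)
                        pred = np.where(d > 0, 1, 0)
                        # reference: true rule on correct trials; the rule the
                        # animal's choice implies (the other rule) on errors
                        ref = ri if kind == "correct" else 1 - ri
                        records[(rule.value, kind, es_name)].append(
                            float(np.mean(pred == ref))
                        )
        rows = []
        for (rule, kind, es), vals in records.items():
            vals = np.asarray(vals)
            rows.append(
                {
                    "rule": rule,
                    "trials": kind,
                    "epoch_set": es,
                    "cp_mean": vals.mean(),
                    "cp_sem": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "n_neurons": len(pools),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DecodeResult:
    """Container for decoding outputs with JSON/CSV serialization."""

    curve: Optional[pd.DataFrame] = None
    variants: dict[str, float] = field(default_factory=dict)
    exclusion: Optional[pd.DataFrame] = None
    error_cp: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {"variants": self.variants, "meta": self.meta}
        if self.curve is not None:
            d["curve"] = self.curve.to_dict(orient="list")
        if self.exclusion is not None:
            d["exclusion"] = self.exclusion.to_dict(orient="list")
        if self.error_cp is not None:
            d["error_cp"] = self.error_cp.to_dict(orient="list")
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True, default=float) + "\n")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.curve is not None:
            self.curve.to_csv(directory / "accuracy_vs_n.csv", index=False)
        if self.exclusion is not None:
            self.exclusion.to_csv(directory / "type_exclusion.csv", index=False)
        if self.error_cp is not None:
            self.error_cp.to_csv(directory / "choice_probability.csv", index=False)
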