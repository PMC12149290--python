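"""Synthetic-benchmark suite: recovery and calibration checks for the pipeline.

Every function here runs the package end-to-end on generator output under
the study conditions (neuron gain 8 spikes/s over a 5 spikes/s baseline,
realistic error and reaction-time structure, stimulation erasure
probability 0.3) and returns the measured quantity.  The acceptance script
and the acceptance tests both call these functions; nothing is precomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import (
    condition_table,
    stimulation_effect_test,
    theta_records,
    theta_session_stats,
)
from .decoding import RuleDecoder, assemble_pseudopopulation, build_neuron_pool
from .encoding import (
    DESIGN_COLUMNS,
    build_design,
    fit_poisson_glm,
    fit_session,
)
from .simulate import (
    Archetype,
    BehaviorSpec,
    NeuronSpec,
    default_neuron_panel,
    generate_session,
    generate_trials,
    simulate_choice,
)
from .task import Rule, TaskConfig


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# structural worked examples
# ---------------------------------------------------------------------------

def design_structure(seed: int = 0) -> dict:
    """Rows-per-delay / column counts and the worked dummy codings."""
    import dataclasses

    config = TaskConfig()
    trials = generate_trials(config, 25, seed=seed)
    empty = pd.DataFrame(columns=["trial_id", "delay_index", "epoch", "count"])
    X, _ = build_design(trials, empty)
    n_delays = sum(t.n_cues for t in trials)

    # worked examples: a cue in the upper-right location (index 0) and the
    # lower-left memory (index 2) becoming obsolete at the following cue
    tr = dataclasses.replace(
        trials[0], rule=Rule.ONE_BACK, cue_locations=[2, 0],
        cue_onsets=trials[0].cue_onsets[:2],
        fp_offset_time=trials[0].cue_onsets[1] + 950,
    )
    Xw, _ = build_design([tr], empty)
    vis_row = Xw.iloc[2][["vis_0", "vis_1", "vis_2", "vis_3"]].tolist()
    ext_row = Xw.iloc[2][["ext_0", "ext_1", "ext_2", "ext_3"]].tolist()
    return {
        "n_columns": len(X.columns),
        "rows_per_delay": len(X) / n_delays,
        "visual_dummy_upper_right": vis_row,
        "extinction_dummy_lower_left": ext_row,
        "visual_dummy_matches": float(vis_row == [1, 0, 0, 0]),
        "extinction_dummy_matches": float(ext_row == [0, 0, 1, 0]),
    }


def decoder_protocol_structure(seed: int = 0) -> dict:
    """Training data points per neuron in one classifier instance (4 x 8 x 2)."""
    config = TaskConfig()
    specs = [NeuronSpec(i, Archetype.MEMORY, preferred_location=i % 4)
             for i in range(3)]
    bundle = generate_session(config, 350, specs, seed=seed, with_eye=False)
    pools = [build_neuron_pool(bundle, s.neuron_id, s.preferred_location)
             for s in specs]
    tensor = assemble_pseudopopulation(pools)
    X, y = RuleDecoder(tensor).training_design(seed=seed)
    return {
        "training_points_per_neuron": X.size / tensor.n_neurons,
        "training_rows": X.shape[0],
        "epochs_per_neuron": X.shape[1] / tensor.n_neurons,
        "labels_balanced": float(int(y.sum()) * 2 == len(y)),
    }


# ---------------------------------------------------------------------------
# GLM recovery and calibration
# ---------------------------------------------------------------------------

def _recovery_truth() -> pd.Series:
    """A ground-truth coefficient vector in the identified parameter space
    (visual block sums to zero; see the encoding-model docs)."""
    truth = pd.Series(0.0, index=DESIGN_COLUMNS)
    truth[["vis_0", "vis_1", "vis_2", "vis_3"]] = [0.6, -0.1, -0.3, -0.2]
    truth[["ext_0", "ext_2"]] = [0.5, -0.2]
    truth[["mem_0", "mem_1", "mem_3"]] = [0.8, -0.2, 0.3]
    truth["order_early"], truth["order_late"] = 0.3, -0.2
    truth["rule_early"], truth["rule_late"] = 0.2, 0.4
    truth["bias_early"], truth["bias_late"] = 0.9, 1.0
    return truth


def glm_parameter_recovery(seed: int, n_trials: int = 400) -> dict:
    """Median absolute coefficient error on data simulated from known betas."""
    config = TaskConfig()
    rng = np.random.default_rng(seed)
    trials = generate_trials(config, n_trials, seed=seed)
    empty = pd.DataFrame(columns=["trial_id", "delay_index", "epoch", "count"])
    X, _ = build_design(trials, empty)
    truth = _recovery_truth()
    y = rng.poisson(np.exp(X.to_numpy() @ truth.to_numpy())).astype(float)
    fit = fit_poisson_glm(X, y)
    err = np.abs(fit.params - truth)
    return {
        "median_abs_beta_error": float(np.nanmedian(err)),
        "converged": float(fit.converged),
    }


def glm_null_calibration(seed: int, n_reps: int = 1000,
                         n_trials: int = 400) -> dict:
    """Per-coefficient Wald type-I error under a bias-only null model."""
    config = TaskConfig()
    rng = np.random.default_rng(seed)
    trials = generate_trials(config, n_trials, seed=seed)
    empty = pd.DataFrame(columns=["trial_id", "delay_index", "epoch", "count"])
    X, _ = build_design(trials, empty)
    Xm = X.to_numpy()
    null = pd.Series(0.0, index=DESIGN_COLUMNS)
    null["bias_early"] = null["bias_late"] = np.log(2.0)
    mu = np.exp(Xm @ null.to_numpy())
    tested = [c for c in DESIGN_COLUMNS if not c.startswith("bias")]
    hits = pd.Series(0, index=tested, dtype=float)
    for _ in range(n_reps):
        y = rng.poisson(mu).astype(float)
        fit = fit_poisson_glm(X, y)
        hits += (fit.pvalues[tested] < 0.05).astype(float)
    rates = hits / n_reps
    return {
        "type1_median": float(rates.median()),
        "type1_mean": float(rates.mean()),
        "type1_min": float(rates.min()),
        "type1_max": float(rates.max()),
        "per_coefficient": rates.to_dict(),
    }


# ---------------------------------------------------------------------------
# neuron-type recovery
# ---------------------------------------------------------------------------

def neuron_type_recovery(
    seed: int,
    n_sessions: int = 2,
    n_per_archetype: int = 20,
    n_trials: int = 500,
    gain: float = 8.0,
    baseline: float = 5.0,
) -> dict:
    """Directional-label and preferred-location recovery on generator output."""
    got, loc_ok = [], []
    for s in _seeds(seed, n_sessions):
        specs = default_neuron_panel(
            n_per_archetype,
            archetypes=(Archetype.MEMORY, Archetype.EXTINCTION,
                        Archetype.VISUAL, Archetype.NULL),
            baseline_rate=baseline, gain=gain,
        )
        bundle = generate_session(TaskConfig(), n_trials, specs, seed=s,
                                  with_eye=False)
        table = fit_session(bundle)
        truth = {sp.neuron_id: sp for sp in specs}
        for _, r in table.iterrows():
            sp = truth[int(r["neuron_id"])]
            if sp.archetype is Archetype.NULL:
                continue
            name = sp.archetype.value
            ok = bool(r["included"]) and not bool(r["flagged"]) and bool(
                r[f"directional_{name}"])
            got.append(ok)
            if ok:
                loc_ok.append(int(r[f"pref_loc_{name}"]) == sp.preferred_location)
    return {
        "directional_label_recovery": float(np.mean(got)),
        "preferred_location_exact": float(np.mean(loc_ok)) if loc_ok else np.nan,
        "n_neurons": len(got),
    }


# ---------------------------------------------------------------------------
# decoding calibration, ordering, exclusion
# ---------------------------------------------------------------------------

def _decode_session_tensor(seed: int, n_trials: int = 450):
    """A mixed-archetype session and its pseudo-population tensor."""
    specs = default_neuron_panel(
        20,
        archetypes=(Archetype.MEMORY, Archetype.EXTINCTION, Archetype.VISUAL,
                    Archetype.ORDER, Archetype.NULL),
    )
    bundle = generate_session(TaskConfig(), n_trials, specs, seed=seed,
                              with_eye=False)
    pools = [build_neuron_pool(bundle, s.neuron_id, s.preferred_location)
             for s in specs]
    tensor = assemble_pseudopopulation(pools)
    types = {
        arch.value: {s.neuron_id for s in specs if s.archetype is arch}
        for arch in (Archetype.MEMORY, Archetype.EXTINCTION, Archetype.VISUAL,
                     Archetype.ORDER, Archetype.NULL)
    }
    return tensor, types


def decoding_calibration_and_ordering(seed: int, n_seeds: int = 20) -> dict:
    """Shuffled-label chance calibration and 10-vs-50-neuron ordering."""
    tensor, _ = _decode_session_tensor(seed)
    decoder = RuleDecoder(tensor)
    ci = 1.96 * np.sqrt(0.25 / 100)       # binomial CI of 0.5 at 100 draws
    shuffled_means, monotone = [], []
    for s in _seeds(seed + 1, n_seeds):
        sh = decoder.accuracy_distribution(10, seed=s, n_repeats=25,
                                           shuffle_labels=True)
        shuffled_means.append(sh.mean())
        a10 = decoder.accuracy_distribution(10, seed=s + 1, n_repeats=25)
        a50 = decoder.accuracy_distribution(50, seed=s + 2, n_repeats=25)
        monotone.append(a50.mean() >= a10.mean())
    shuffled_means = np.asarray(shuffled_means)
    return {
        "shuffled_mean": float(shuffled_means.mean()),
        "shuffled_within_ci": float(np.mean(np.abs(shuffled_means - 0.5) <= ci)),
        "monotone_fraction": float(np.mean(monotone)),
        "n_neurons_available": tensor.n_neurons,
    }


def decoding_type_exclusion(seed: int, n_fixed: int = 67,
                            n_repeats: int = 100) -> dict:
    """Accuracy drop from excluding each archetype at fixed population size."""
    tensor, types = _decode_session_tensor(seed)
    decoder = RuleDecoder(tensor)
    res = decoder.type_exclusion_deltas(types, n_fixed=n_fixed, seed=seed + 7,
                                        n_repeats=n_repeats)
    res = res.set_index("type")
    deltas = res["delta"].dropna()
    return {
        "largest_drop_type": str(deltas.idxmax()),
        "memory_drop_is_largest": float(deltas.idxmax() == "memory"),
        "memory_delta": float(res.loc["memory", "delta"]),
        "deltas": deltas.to_dict(),
    }


# ---------------------------------------------------------------------------
# behavioral recovery
# ---------------------------------------------------------------------------

def theta_bias_recovery(seed: int, n_sessions: int = 100,
                        trials_per_rule: int = 300) -> dict:
    """Recovery of the generated 2-back-minus-1-back trajectory bias (-3 deg)."""
    config = TaskConfig()
    bs = BehaviorSpec()          # theta bias +1 deg (1-back) vs -2 deg (2-back)
    truth_delta = bs.theta_bias_mean[Rule.TWO_BACK] - bs.theta_bias_mean[Rule.ONE_BACK]
    deltas = []
    for s in _seeds(seed, n_sessions):
        rng = np.random.default_rng(s)
        trials = generate_trials(config, 2 * trials_per_rule, seed=rng)
        outcomes = [simulate_choice(t, bs, config, rng)[0] for t in trials]
        stats_ = theta_session_stats(theta_records(trials, outcomes, config))
        deltas.append(stats_["delta_theta"])
    deltas = np.asarray(deltas)
    se = deltas.std(ddof=1) / np.sqrt(len(deltas))
    return {
        "true_delta_deg": float(truth_delta),
        "recovered_delta_deg": float(deltas.mean()),
        "se_deg": float(se),
        "abs_error_deg": float(abs(deltas.mean() - truth_delta)),
        "within_2se": float(abs(deltas.mean() - truth_delta) <= 2 * se),
        "sign_recovery_fraction": float(np.mean(deltas < 0)),
    }


def stimulation_specificity(
    seed: int,
    n_experiments: int = 100,
    n_sessions: int = 17,
    trials_per_cell: int = 60,
    stim_p_erase: float = 0.3,
) -> dict:
    """Fraction of experiments flagging only the 2-back/contra condition.

    Each experiment simulates ``n_sessions`` stimulation sessions with about
    ``trials_per_cell`` trials in every (condition x stim) cell and runs the
    stimulation-effect test; success means the 2-back contra-last-1
    condition is significant while the 1-back contra and 2-back ipsi
    conditions are not.
    """
    config = TaskConfig()
    bs = BehaviorSpec(stim_p_erase=stim_p_erase)
    n_trials = trials_per_cell * 8       # 2 rules x 2 hemifields x 2 stim arms
    only_target = []
    for s in _seeds(seed, n_experiments):
        rng = np.random.default_rng(s)
        tables = []
        for j in range(n_sessions):
            trials = generate_trials(config, n_trials, stim_fraction=0.5,
                                     seed=rng)
            outcomes = [simulate_choice(t, bs, config, rng)[0] for t in trials]
            tables.append(condition_table(trials, outcomes, config,
                                          session_id=f"s{j}"))
        res = stimulation_effect_test(pd.concat(tables, ignore_index=True))
        res = res.set_index(["rule", "last1_hemi"])
        ok = (
            bool(res.loc[("2-back", "contra"), "error_significant"])
            and not bool(res.loc[("1-back", "contra"), "error_significant"])
            and not bool(res.loc[("2-back", "ipsi"), "error_significant"])
        )
        only_target.append(ok)
    return {
        "specificity_fraction": float(np.mean(only_target)),
        "n_experiments": n_experiments,
    }
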