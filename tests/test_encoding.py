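"""Encoding model: design construction, Poisson GLM fit, DI, classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from oculonback import (
    EncodingModel,
    build_design,
    directional_index,
    fit_poisson_glm,
    fit_session,
    generate_session,
    generate_trials,
)
from oculonback.encoding import (
    COMPONENT_COLUMNS,
    DESIGN_COLUMNS,
    _constraint_map,
    poisson_deviance,
)
from oculonback.simulate import Archetype, NeuronSpec
from oculonback.spikes import epoch_counts
from oculonback.task import Rule


def empty_counts():
    return pd.DataFrame(columns=["trial_id", "delay_index", "epoch", "count"])


def one_trial(task_config, rule, cues):
    tr = generate_trials(task_config, 1, seed=0)[0]
    onsets = [tr.cue_onsets[0] + 950 * k for k in range(len(cues))]
    return dataclasses.replace(tr, rule=rule, cue_locations=list(cues),
                               cue_onsets=onsets,
                               fp_offset_time=onsets[-1] + 950)


class TestDesign:
    def test_worked_dummy_codings(self, task_config):
        # upper-right cue (index 0) -> visual [1 0 0 0]; the lower-left
        # memory (index 2) dropping at cue 2 -> extinction [0 0 1 0]
        tr = one_trial(task_config, Rule.ONE_BACK, [0, 2, 3])
        X, _ = build_design([tr], empty_counts())
        early1 = X.iloc[0]
        assert list(early1[["vis_0", "vis_1", "vis_2", "vis_3"]]) == [1, 0, 0, 0]
        assert list(early1[["ext_0", "ext_1", "ext_2", "ext_3"]]) == [0, 0, 0, 0]
        early3 = X.iloc[4]    # delay 3 early row: memory of lower-left dropped
        assert list(early3[["ext_0", "ext_1", "ext_2", "ext_3"]]) == [0, 0, 1, 0]

    def test_18_columns_two_rows_per_delay(self, task_config):
        trials = generate_trials(task_config, 40, seed=1)
        X, y = build_design(trials, empty_counts())
        assert list(X.columns) == DESIGN_COLUMNS
        assert len(DESIGN_COLUMNS) == 18
        assert len(X) == sum(2 * t.n_cues for t in trials) == len(y)

    def test_row_invariants_over_random_trials(self, task_config):
        trials = generate_trials(task_config, 500, seed=2)
        X, _ = build_design(trials, empty_counts())
        early = X.iloc[0::2]
        late = X.iloc[1::2]
        mem_cols = COMPONENT_COLUMNS["memory"]
        vis_cols = COMPONENT_COLUMNS["visual"]
        ext_cols = COMPONENT_COLUMNS["extinction"]
        assert (early[mem_cols].to_numpy() == 0).all()
        assert (late[vis_cols].to_numpy() == 0).all()
        assert (late[ext_cols].to_numpy() == 0).all()
        assert (early[vis_cols].sum(axis=1) == 1).all()
        assert (early[ext_cols].sum(axis=1) <= 1).all()
        assert late[mem_cols].sum(axis=1).isin([1, 2]).all()
        for col in ("order_early", "rule_early"):
            assert early[col].between(0, 1).all()

    def test_two_back_duplicate_memory_collapses(self, task_config):
        tr = one_trial(task_config, Rule.TWO_BACK, [1, 1])
        X, _ = build_design([tr], empty_counts())
        late2 = X.iloc[3]
        assert late2["mem_1"] == 1.0
        assert late2[["mem_0", "mem_2", "mem_3"]].sum() == 0.0

    def test_unclassified_trials_excluded(self, task_config):
        from oculonback.task import ChoiceCategory, ChoiceOutcome

        trials = generate_trials(task_config, 4, seed=3)
        outs = [ChoiceOutcome(0, ChoiceCategory.CORRECT)] * 3 + [
            ChoiceOutcome(None, ChoiceCategory.FIXATION_BREAK)
        ]
        X, _ = build_design(trials, empty_counts(), outs)
        assert len(X) == sum(2 * t.n_cues for t in trials[:3])


class TestPoissonFit:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"bias_early": np.ones(200)})
        y = np.full(200, 7.0)
        fit = fit_poisson_glm(X, y)
        assert fit.params["bias_early"] == pytest.approx(np.log(7.0), abs=1e-6)
        assert fit.converged

    def test_all_zero_columns_reported_absent(self):
        X = pd.DataFrame({"bias_early": np.ones(50), "ext_0": np.zeros(50)})
        fit = fit_poisson_glm(X, np.full(50, 3.0))
        assert np.isnan(fit.params["ext_0"])
        assert fit.dropped == ["ext_0"]

    def test_deviance_monotone_nonincreasing(self, task_config, rng):
        trials = generate_trials(task_config, 120, seed=4)
        X, _ = build_design(trials, empty_counts())
        mu = np.exp(0.8 + 0.5 * X["mem_1"].to_numpy() + 0.3 * X["vis_2"].to_numpy())
        y = rng.poisson(mu).astype(float)
        fit = fit_poisson_glm(X, y)
        dev = np.array(fit.deviance_history)
        assert np.all(np.diff(dev) <= 1e-9)
        assert fit.converged

    def test_matches_statsmodels_oracle(self, task_config, rng):
        """The damped IRLS solution agrees with statsmodels GLM fitted on the
        identified (visual sum-to-zero) reparametrization."""
        import statsmodels.api as sm

        trials = generate_trials(task_config, 150, seed=5)
        X, _ = build_design(trials, empty_counts())
        mu = np.exp(0.7 + 0.6 * X["mem_0"].to_numpy() - 0.2 * X["rule_late"].to_numpy())
        y = rng.poisson(mu).astype(float)
        fit = fit_poisson_glm(X, y)

        nz = [c for c in X.columns if (X[c] != 0).any()]
        T = _constraint_map(nz)
        Xr = X[nz].to_numpy() @ T
        res = sm.GLM(y, Xr, family=sm.families.Poisson()).fit(method="lbfgs",
                                                              maxiter=500, disp=0)
        beta_sm = T @ res.params
        ours = fit.params[nz].to_numpy()
        assert np.allclose(ours, beta_sm, atol=2e-4)
        # deviance at the optimum agrees too
        mu_hat = np.exp(X[nz].to_numpy() @ ours)
        assert poisson_deviance(y, mu_hat) == pytest.approx(res.deviance, rel=1e-6)

    def test_parameter_recovery_sanity(self, task_config, rng):
        trials = generate_trials(task_config, 300, seed=6)
        X, _ = build_design(trials, empty_counts())
        truth = pd.Series(0.0, index=DESIGN_COLUMNS)
        truth[["vis_0", "vis_1", "vis_2", "vis_3"]] = [0.6, -0.2, -0.2, -0.2]
        truth[["mem_0", "mem_2"]] = [0.8, -0.3]
        truth[["bias_early", "bias_late"]] = [0.9, 1.1]
        truth["rule_late"] = 0.4
        y = rng.poisson(np.exp(X.to_numpy() @ truth.to_numpy())).astype(float)
        fit = fit_poisson_glm(X, y)
        err = np.abs(fit.params - truth)
        assert np.nanmedian(err) < 0.1


class TestDirectionalIndex:
    angles = (45.0, 135.0, 225.0, 315.0)

    def test_single_beta_full_di(self):
        di, ang = directional_index([1, 0, 0, 0], self.angles)
        assert di == pytest.approx(1.0)
        assert ang == pytest.approx(45.0)

    def test_symmetric_betas_zero_di(self):
        di, ang = directional_index([1, 1, 1, 1], self.angles)
        assert di == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_returns_zero(self):
        di, ang = directional_index([0, 0, 0, 0], self.angles)
        assert di == 0.0 and ang is None

    def test_scale_invariance(self, rng):
        for _ in range(1000):
            b = rng.normal(0, 1, 4)
            c = rng.uniform(0.1, 10)
            di1, a1 = directional_index(b, self.angles)
            di2, a2 = directional_index(b * c, self.angles)
            assert di1 == pytest.approx(di2, abs=1e-12)
            if a1 is not None:
                assert a1 == pytest.approx(a2, abs=1e-9)

    def test_nan_betas_treated_as_absent(self):
        di, ang = directional_index([1.0, np.nan, np.nan, np.nan], self.angles)
        assert di == pytest.approx(1.0)

    def test_max_norm_variant(self):
        di_l1, _ = directional_index([2, 0, 0, 0], self.angles, norm="l1")
        di_mx, _ = directional_index([2, 0, 0, 0], self.angles, norm="max")
        assert di_l1 == pytest.approx(1.0)
        assert di_mx == pytest.approx(0.25)


class TestClassification:
    def test_model_results_roundtrip(self, glm_session):
        res = EncodingModel.from_session(glm_session, 0).fit()
        assert res.converged
        txt = res.summary()
        assert "bias_early" in txt and "significant components" in txt
        labels = res.classify("left")
        assert "memory" in labels.significant

    def test_mixed_archetype_gets_both_labels(self, task_config):
        """A memory+extinction mixture carries both directional labels."""
        specs = [NeuronSpec(i, Archetype.MIXED, preferred_location=0,
                            gain=16.0,
                            mixture_weights={"memory": 0.5, "extinction": 0.5})
                 for i in range(3)]
        b = generate_session(task_config, 400, specs, seed=31, with_eye=False)
        hits = 0
        for nid in range(3):
            labels = EncodingModel.from_session(b, nid).fit().classify("left")
            if {"memory", "extinction"} <= labels.directional:
                hits += 1
        assert hits >= 2

    def test_null_neurons_rarely_directional(self, glm_session):
        """NULL archetypes that survive screening get directional labels at
        no more than the nominal any-of-four false-positive rate."""
        tab = fit_session(glm_session)
        truth = {s.neuron_id: s.archetype for s in glm_session.truth.neuron_specs}
        null_rows = tab[[truth[i] is Archetype.NULL for i in tab["neuron_id"]]]
        # most nulls are screened out entirely
        assert null_rows["included"].mean() < 0.5
        inc = null_rows[null_rows["included"].astype(bool)]
        if len(inc):
            false_dir = (
                inc[["directional_visual", "directional_extinction",
                     "directional_memory"]].astype(bool).any(axis=1)
            )
            assert false_dir.mean() <= 0.5

    def test_generated_types_recovered(self, glm_session):
        tab = fit_session(glm_session)
        truth = {s.neuron_id: s for s in glm_session.truth.neuron_specs}
        got, loc_ok = [], []
        for _, r in tab.iterrows():
            s = truth[int(r["neuron_id"])]
            if s.archetype is Archetype.NULL:
                continue
            name = s.archetype.value
            ok = bool(r["included"]) and not bool(r["flagged"]) and bool(
                r[f"directional_{name}"])
            got.append(ok)
            if ok:
                loc_ok.append(int(r[f"pref_loc_{name}"]) == s.preferred_location)
        assert np.mean(got) >= 0.75          # small-session sanity level
        assert np.mean(loc_ok) >= 0.9

    def test_flagged_fit_left_unclassified(self):
        from oculonback.encoding import ComponentFit, classify_neuron

        params = pd.Series(np.nan, index=DESIGN_COLUMNS)
        fit = ComponentFit(params, params.copy(), params.copy(), False, True,
                           [], 0, [])
        labels = classify_neuron(fit, (45, 135, 225, 315), "left")
        assert labels.unclassified
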