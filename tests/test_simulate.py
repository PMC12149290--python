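"""Synthetic session generator: trials, rates, spikes, choices, eye traces."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from oculonback import (
    BehaviorSpec,
    ChoiceCategory,
    NeuronSpec,
    Rule,
    Stimulation,
    TaskConfig,
    classify_choice,
    generate_session,
    generate_trials,
    rate_profile,
    sample_spikes,
    simulate_choice,
    synthesize_eye_trace,
)
from oculonback.behavior import detect_saccades
from oculonback.simulate import Archetype, PiecewiseRate, default_neuron_panel


def spec_of(arch, pref=0, **kw):
    return NeuronSpec(0, arch, preferred_location=pref, **kw)


class TestGenerateTrials:
    def test_single_trial(self, task_config):
        assert len(generate_trials(task_config, 1, seed=0)) == 1

    def test_location_marginals_uniform(self, task_config):
        trials = generate_trials(task_config, 10_000, seed=5)
        locs = np.concatenate([t.cue_locations for t in trials])
        freqs = np.bincount(locs, minlength=4) / len(locs)
        # binomial CI around 1/4 at this n is about +/- 0.005; allow 4 sigma
        assert np.all(np.abs(freqs - 0.25) < 4 * np.sqrt(0.25 * 0.75 / len(locs)))

    def test_stim_fraction_binomial(self, task_config):
        trials = generate_trials(task_config, 2000, stim_fraction=0.5, seed=6)
        n_stim = sum(t.stimulation is not Stimulation.NONE for t in trials)
        assert abs(n_stim - 1000) < 4 * np.sqrt(2000 * 0.25)

    def test_empty_rule_mix_rejected(self, task_config):
        with pytest.raises(ValueError):
            generate_trials(task_config, 5, rule_mix={}, seed=0)

    def test_seed_determinism(self, task_config):
        a = generate_trials(task_config, 50, seed=9)
        b = generate_trials(task_config, 50, seed=9)
        assert a == b


class TestRateProfile:
    def test_null_constant_baseline(self, task_config):
        tr = generate_trials(task_config, 1, seed=0)[0]
        prof = rate_profile(spec_of(Archetype.NULL), tr, task_config)
        assert np.allclose(prof.rates, prof.rates[0])

    def test_memory_one_back_elevated_first_delay_only(self, task_config):
        tr = generate_trials(task_config, 1, seed=0)[0]
        tr = dataclasses.replace(tr, rule=Rule.ONE_BACK, cue_locations=[0, 1],
                                 cue_onsets=tr.cue_onsets[:2],
                                 fp_offset_time=tr.cue_onsets[1] + 950)
        spec = spec_of(Archetype.MEMORY, pref=0, baseline_rate=5, gain=8)
        prof = rate_profile(spec, tr, task_config)
        d1 = tr.cue_onsets[0] + 150 + 200      # inside delay 1
        d2 = tr.cue_onsets[1] + 150 + 200      # inside delay 2
        assert prof(d1) == pytest.approx(13.0)
        assert prof(d2) == pytest.approx(5.0)

    def test_memory_two_back_persists_two_delays(self, task_config):
        tr = generate_trials(task_config, 1, seed=0)[0]
        onsets = [tr.cue_onsets[0] + 950 * k for k in range(3)]
        tr = dataclasses.replace(tr, rule=Rule.TWO_BACK, cue_locations=[0, 1, 1],
                                 cue_onsets=onsets, fp_offset_time=onsets[-1] + 950)
        prof = rate_profile(spec_of(Archetype.MEMORY, pref=0), tr, task_config)
        mids = [on + 150 + 200 for on in onsets]
        assert prof(mids[0]) == pytest.approx(13.0)
        assert prof(mids[1]) == pytest.approx(13.0)
        assert prof(mids[2]) == pytest.approx(5.0)

    def test_mixed_weights_combine(self, task_config):
        tr = generate_trials(task_config, 1, seed=0)[0]
        spec = NeuronSpec(0, Archetype.MIXED, preferred_location=tr.cue_locations[0],
                          mixture_weights={"visual": 0.5, "null": 0.5})
        prof = rate_profile(spec, tr, task_config)
        just_after_cue = tr.cue_onsets[0] + 100
        assert prof(just_after_cue) == pytest.approx(5.0 + 0.5 * 8.0)


class TestSampleSpikes:
    def test_zero_rate_empty(self, rng):
        prof = PiecewiseRate(np.array([0.0, 1000.0]), np.array([0.0]))
        assert len(sample_spikes(prof, (0, 1000), rng)) == 0

    def test_poisson_moments(self, rng):
        prof = PiecewiseRate(np.array([0.0, 1000.0]), np.array([20.0]))
        counts = [len(sample_spikes(prof, (0, 1000), rng)) for _ in range(3000)]
        assert np.mean(counts) == pytest.approx(20.0, abs=0.5)
        assert np.var(counts) == pytest.approx(20.0, rel=0.15)

    def test_rate_scaling(self, rng):
        prof2 = PiecewiseRate(np.array([0.0, 5000.0]), np.array([40.0]))
        counts = [len(sample_spikes(prof2, (0, 5000), rng)) for _ in range(500)]
        assert np.mean(counts) == pytest.approx(200.0, rel=0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseRate(np.array([0.0, 1.0]), np.array([-1.0]))

    def test_callable_requires_bound(self, rng):
        with pytest.raises(ValueError):
            sample_spikes(lambda t: np.full_like(t, 5.0), (0, 100), rng)

    def test_thinning_matches_callable(self, rng):
        f = lambda t: 10.0 + 10.0 * (np.asarray(t) > 500)
        counts = [
            len(sample_spikes(f, (0, 1000), rng, bound=20.0)) for _ in range(2000)
        ]
        assert np.mean(counts) == pytest.approx(15.0, abs=0.4)


class TestSimulateChoice:
    def test_all_correct_when_error_free(self, task_config, rng):
        bs = BehaviorSpec()
        for r in Rule:
            bs.p_rule_error[r] = bs.p_mem_23back[r] = 0.0
            bs.p_mem_random[r] = bs.p_fixation_break[r] = 0.0
        for tr in generate_trials(task_config, 100, seed=2):
            out, erased = simulate_choice(tr, bs, task_config, rng)
            assert out.category is ChoiceCategory.CORRECT
            assert erased is None

    def test_guaranteed_erasure_two_back_contra(self, task_config, rng):
        bs = BehaviorSpec(stim_p_erase=1.0)
        for r in Rule:
            bs.p_fixation_break[r] = 0.0
        trials = generate_trials(task_config, 400, stim_fraction=1.0, seed=3)
        hit = 0
        for tr in trials:
            if tr.rule is not Rule.TWO_BACK:
                continue
            if tr.hemifield_map[tr.cue_locations[-2]] != "contra":
                continue
            out, erased = simulate_choice(tr, bs, task_config, rng)
            hit += 1
            assert erased == tr.cue_locations[-2]
            assert out.chosen_location == tr.cue_locations[-1]
            if tr.cue_locations[-1] != tr.cue_locations[-2]:
                assert out.category is ChoiceCategory.RULE_ERROR
        assert hit > 10

    def test_early_stim_spares_one_back(self, task_config, rng):
        bs = BehaviorSpec(stim_p_erase=1.0)
        trials = generate_trials(task_config, 200, stim_fraction=1.0, seed=4)
        for tr in trials:
            if tr.rule is Rule.ONE_BACK:
                _, erased = simulate_choice(tr, bs, task_config, rng)
                assert erased is None

    def test_category_frequencies_chi2(self, task_config):
        """Generated category frequencies match BehaviorSpec probabilities."""
        bs = BehaviorSpec()
        rng = np.random.default_rng(11)
        trials = generate_trials(task_config, 5000, seed=11)
        for rule in Rule:
            sub = [t for t in trials if t.rule is rule]
            cats = [simulate_choice(t, bs, task_config, rng)[0].category for t in sub]
            n = len(cats)
            # compare against expected (fold rules shift a little mass between
            # the two memory-error bins, so pool them)
            p_fb = bs.p_fixation_break[rule]
            p_re = bs.p_rule_error[rule] * 15 / 16       # last-two-equal folds out
            p_me = bs.p_mem_23back[rule] + bs.p_mem_random[rule]
            expected = np.array([p_fb, (1 - p_fb) * p_re, (1 - p_fb) * p_me])
            expected = np.append(expected, 1 - expected.sum()) * n
            observed = np.array([
                sum(c is ChoiceCategory.FIXATION_BREAK for c in cats),
                sum(c is ChoiceCategory.RULE_ERROR for c in cats),
                sum(c in (ChoiceCategory.MEM_ERROR_23BACK,
                          ChoiceCategory.MEM_ERROR_RANDOM) for c in cats),
            ])
            observed = np.append(observed, n - observed.sum())
            _, p = stats.chisquare(observed, expected)
            assert p > 0.01


class TestEyeTraces:
    def test_no_response_trace_quiet(self, task_config, rng):
        tr = generate_trials(task_config, 1, seed=0)[0]
        from oculonback.task import ChoiceOutcome

        out = ChoiceOutcome(None, ChoiceCategory.NO_RESPONSE)
        eye = synthesize_eye_trace(tr, out, BehaviorSpec(), task_config, rng)
        assert len(detect_saccades(eye)) == 0

    def test_noise_free_endpoint_exact(self, task_config, rng):
        from oculonback.task import ChoiceOutcome

        tr = generate_trials(task_config, 1, seed=0)[0]
        target = task_config.location_xy(2)
        out = ChoiceOutcome(2, ChoiceCategory.CORRECT, reaction_time=200.0,
                            endpoint=target)
        eye = synthesize_eye_trace(tr, out, BehaviorSpec(), task_config, rng,
                                   fixation_sd=0.0)
        assert eye[-1, 1] == pytest.approx(target[0], abs=1e-9)
        assert eye[-1, 2] == pytest.approx(target[1], abs=1e-9)

    def test_detection_roundtrip_rt_and_endpoint(self, task_config):
        """Noise-free generated saccades are recovered within 5 ms / 0.2 deg."""
        rng = np.random.default_rng(21)
        bs = BehaviorSpec()
        trials = generate_trials(task_config, 100, seed=21)
        checked = 0
        for tr in trials:
            out, _ = simulate_choice(tr, bs, task_config, rng)
            if out.category in (ChoiceCategory.FIXATION_BREAK,
                                ChoiceCategory.NO_RESPONSE):
                continue
            eye = synthesize_eye_trace(tr, out, bs, task_config, rng,
                                       fixation_sd=0.0)
            evs = [e for e in detect_saccades(eye)
                   if e.onset >= tr.fp_offset_time]
            assert len(evs) == 1
            ev = evs[0]
            assert abs(ev.onset - tr.fp_offset_time - out.reaction_time) <= 5.0
            assert np.hypot(ev.end[0] - out.endpoint[0],
                            ev.end[1] - out.endpoint[1]) <= 0.2
            checked += 1
        assert checked > 50


class TestSessionDeterminism:
    def test_identical_seed_identical_session(self, task_config, tmp_path):
        from oculonback.io import write_session

        specs = default_neuron_panel(1, archetypes=(Archetype.MEMORY,
                                                    Archetype.NULL))
        hashes = []
        for d in ("a", "b"):
            bundle = generate_session(task_config, 25, specs, seed=99,
                                      stim_fraction=0.3)
            p = write_session(bundle, tmp_path / d)
            blob = b"".join(
                sorted(f.read_bytes() for f in p.iterdir() if f.is_file())
            )
            hashes.append(hash(blob))
        assert hashes[0] == hashes[1]

    def test_outcome_conservation_and_sorted_spikes(self, small_session):
        b = small_session
        assert len(b.outcomes) == len(b.trials)
        for nid in b.neuron_ids:
            ts = b.spike_times(nid)
            assert np.all(np.diff(ts) > 0)
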