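"""Unit tests for recording, the two replay modes and the Nothing taxonomy."""

import numpy as np
import pytest

from hhreplay.biophysics import NeuronParams, resting_state, _advance_gates, _implicit_voltage
from hhreplay.errors import IncompatibleRecordingError, NotApplicableError
from hhreplay.network import run_simulation
from hhreplay.replay import (
    ClampParams,
    NothingVerdict,
    ReplayMode,
    clamp_charge,
    classify_nothing,
    feedback_clamp_current,
    record_reference_run,
    run_with_replay,
)

from conftest import GREEN, NO_STIM, SEED


class TestRecording:
    def test_recording_equals_open_loop_run_bit_for_bit(self, config, green_recording):
        result = run_simulation(config, GREEN, seed=SEED)
        np.testing.assert_array_equal(green_recording.v, result.v)
        np.testing.assert_array_equal(green_recording.i_lgn, result.i_lgn)

    def test_rerecording_is_deterministic(self, config, green_recording):
        again = record_reference_run(config, GREEN, duration=500.0, seed=SEED)
        np.testing.assert_array_equal(green_recording.v, again.v)

    def test_silent_recording_stays_near_rest(self, config):
        rec = record_reference_run(config, NO_STIM, duration=300.0, seed=SEED)
        assert np.max(np.abs(rec.v - rec.v[:, :1])) < 0.5

    def test_green_recording_contains_spikes_everywhere(self, green_recording):
        assert all(s.size >= 1 for s in green_recording.spikes)


class TestClampCurrent:
    def test_ohmic_arithmetic(self):
        assert feedback_clamp_current(-55.0, -55.0, 0.1) == 0.0
        # 1 mV error across 0.1 MOhm commands 10 nA
        assert feedback_clamp_current(-54.0, -55.0, 0.1) == pytest.approx(1e4)

    def test_clamped_membrane_tracks_a_step_command(self):
        """An isolated clamped cell reaches a command step within 5 RC times."""
        params = NeuronParams()
        rs = 0.05  # MOhm -> tau_clamp = rs*C = 0.01 ms
        g_c = 1000.0 / rs
        tau = rs * params.capacitance / 1000.0
        dt = 0.0025
        state = resting_state(params)
        V, m, h, n = state.V, state.m, state.h, state.n
        cmd = state.V + 10.0
        t, settled_at = 0.0, None
        while t < 1.0:
            m, h, n = _advance_gates(m, h, n, V, params.kinetics, dt)
            V = _implicit_voltage(V, m, h, n, params, dt,
                                  extra_g=g_c, extra_gE=g_c * cmd)
            t += dt
            if settled_at is None and abs(V - cmd) < 0.05 * 10.0:
                settled_at = t
        assert settled_at is not None and settled_at <= 5.0 * tau


class TestReplayFidelity:
    def test_feedback_replay_reproduces_recorded_voltage(self, green_recording, fb_nostim):
        assert np.max(np.abs(fb_nostim.v - green_recording.v)) < 1.0

    def test_feedback_replay_spike_times_match_within_one_step(
            self, green_recording, fb_nostim):
        for sa, sb in zip(fb_nostim.spikes, green_recording.spikes):
            assert sa.size == sb.size
            if sa.size:
                assert np.max(np.abs(sa - sb)) <= fb_nostim.dt

    def test_clamp_current_reconstructs_missing_lgn_input(
            self, green_recording, fb_nostim):
        """I_vc during replay-without-stimulus equals the recorded I_LGN."""
        for i in (0, 1):  # the LGN-driven neurons a and b
            ref = green_recording.i_lgn[i]
            err = (np.sqrt(np.mean((fb_nostim.i_vc[i] - ref) ** 2))
                   / np.sqrt(np.mean(ref ** 2)))
            assert err < 0.05

    def test_feedforward_overwrites_voltage_exactly(self, green_recording, ff_nostim):
        np.testing.assert_array_equal(ff_nostim.v, green_recording.v)

    def test_feedforward_and_feedback_replay_are_equivalent(
            self, ff_nostim, fb_nostim):
        assert np.max(np.abs(ff_nostim.v - fb_nostim.v)) < 1.0
        for sa, sb in zip(ff_nostim.spikes, fb_nostim.spikes):
            np.testing.assert_array_equal(sa, sb)

    def test_mode_off_reproduces_open_loop_run(self, config, green_recording,
                                               clamp_off_green):
        open_loop = run_simulation(config, GREEN, seed=SEED)
        np.testing.assert_array_equal(clamp_off_green.v, open_loop.v)


class TestCounterfactualEraser:
    def test_congruent_replay_injects_nothing(self, congruent_green):
        assert np.max(np.abs(congruent_green.i_vc)) <= 1.0

    def test_incongruent_replay_restores_green_firing(self, incongruent_red):
        assert incongruent_red.firing_count() == 5

    def test_incongruent_replay_recreates_only_the_missing_input(
            self, green_recording, incongruent_red):
        """Neuron a gets the absent LGN drive; b, whose input is present, none."""
        assert np.max(np.abs(incongruent_red.i_vc[0])) > 100.0
        assert np.max(np.abs(incongruent_red.i_vc[1])) <= 1.0
        ref = green_recording.i_lgn[0]
        err = (np.sqrt(np.mean((incongruent_red.i_vc[0] - ref) ** 2))
               / np.sqrt(np.mean(ref ** 2)))
        assert err < 0.05

    def test_nothing_type_i_and_ii_have_identical_activity(
            self, clamp_off_green, congruent_green):
        assert np.max(np.abs(clamp_off_green.v - congruent_green.v)) < 1e-9


class TestNothingClassification:
    def test_clamp_off_is_nothing_type_i(self, clamp_off_green):
        verdict = classify_nothing(ReplayMode.OFF, False, clamp_off_green.i_vc)
        assert verdict is NothingVerdict.NOTHING_TYPE_I

    def test_silent_armed_clamp_is_nothing_type_ii(self, congruent_green):
        verdict = classify_nothing(ReplayMode.FEEDBACK, True, congruent_green.i_vc)
        assert verdict is NothingVerdict.NOTHING_TYPE_II

    def test_active_clamp_is_an_intervention(self, incongruent_red):
        verdict = classify_nothing(ReplayMode.FEEDBACK, True, incongruent_red.i_vc)
        assert verdict is NothingVerdict.INTERVENTION


class TestClampCharge:
    def test_open_loop_charge_is_zero(self, clamp_off_green):
        assert clamp_charge(clamp_off_green).sum() == 0.0

    def test_congruent_charge_is_negligible_vs_incongruent(
            self, congruent_green, incongruent_red):
        assert (clamp_charge(congruent_green).sum()
                < 1e-3 * clamp_charge(incongruent_red).sum())

    def test_feedforward_charge_is_undefined(self, ff_nostim):
        with pytest.raises(NotApplicableError):
            clamp_charge(ff_nostim)


class TestGridCompatibility:
    def test_mismatched_grid_is_rejected(self, config, green_recording):
        import dataclasses
        bad = dataclasses.replace(green_recording, dt=0.05)
        with pytest.raises(IncompatibleRecordingError):
            run_with_replay(config, NO_STIM, bad, ReplayMode.FEEDBACK,
                            ClampParams(), seed=SEED)

    def test_replay_requires_a_recording(self, config):
        with pytest.raises(IncompatibleRecordingError):
            run_with_replay(config, NO_STIM, None, ReplayMode.FEEDBACK,
                            ClampParams(), seed=SEED)

    def test_too_slow_clamp_is_rejected(self, config, green_recording):
        with pytest.raises(ValueError):
            run_with_replay(config, NO_STIM, green_recording, ReplayMode.FEEDBACK,
                            ClampParams(series_resistance=10.0), seed=SEED)
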