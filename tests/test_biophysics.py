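"""Unit tests for the HH neuron and the depressing conductance synapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhreplay.biophysics import (
    NeuronParams,
    NeuronState,
    SynapseParams,
    SynapseState,
    measure_input_resistance,
    resting_state,
    step_neuron,
    synapse_event,
    synapse_step,
    synaptic_conductance,
    synaptic_current,
)
from hhreplay.calibration import (
    fit_decay_tau,
    fit_recovery_tau,
    measure_peak_conductance,
    measure_rise_time,
)
from hhreplay.errors import InvalidProbeError

DT = 0.025


def _count_spikes(vs, threshold=0.0, min_sep_ms=2.0, dt=DT):
    vs = np.asarray(vs)
    cross = np.nonzero((vs[:-1] < threshold) & (vs[1:] >= threshold))[0]
    count, last = 0, -np.inf
    for idx in cross:
        if idx - last >= min_sep_ms / dt:
            count += 1
            last = idx
    return count


def _run_current(params, current_fn, t_end, dt):
    state = resting_state(params)
    vs = [state.V]
    for k in range(int(round(t_end / dt))):
        state = step_neuron(state, params, current_fn(k * dt), dt)
        vs.append(state.V)
    return np.array(vs)


class TestNeuron:
    def test_rest_is_a_fixed_point(self):
        """With zero input the membrane stays at rest for 500 ms."""
        params = NeuronParams()
        v_rest = resting_state(params).V
        vs = _run_current(params, lambda t: 0.0, 500.0, DT)
        assert np.max(np.abs(vs - v_rest)) < 0.01

    def test_sustained_step_current_fires(self):
        """A +300 pA step evokes action potentials that overshoot 0 mV."""
        params = NeuronParams()
        vs = _run_current(params, lambda t: 300.0, 300.0, DT)
        assert _count_spikes(vs) >= 1
        assert vs.max() > 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_spike_count_matches_fine_reference(self, seed):
        """Spike counts at dt agree with a 10x-finer reference integration."""
        rng = np.random.default_rng(seed)
        seg_amps = rng.uniform(0.0, 400.0, size=5)  # 50 ms segments

        def current(t):
            return seg_amps[min(int(t // 50.0), len(seg_amps) - 1)]

        params = NeuronParams()
        coarse = _run_current(params, current, 250.0, DT)
        fine = _run_current(params, current, 250.0, DT / 10.0)
        assert _count_spikes(coarse, dt=DT) == _count_spikes(fine, dt=DT / 10.0)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-2000.0, max_value=2000.0),
                    min_size=3, max_size=8))
    def test_gates_stay_bounded_for_any_input(self, amps):
        """Gate activations remain in [0, 1] under arbitrary current steps."""
        params = NeuronParams()
        state = resting_state(params)
        seg = 40.0  # ms per amplitude segment
        for k in range(int(len(amps) * seg / DT)):
            amp = amps[min(int(k * DT // seg), len(amps) - 1)]
            state = step_neuron(state, params, amp, DT)
            # NeuronState validates bounds on construction; assert explicitly
            assert 0.0 <= state.m <= 1.0
            assert 0.0 <= state.h <= 1.0
            assert 0.0 <= state.n <= 1.0


class TestInputResistance:
    def test_nominal_cell_is_50_mohm(self):
        r = measure_input_resistance(NeuronParams(), probe_current=-20.0)
        assert r == pytest.approx(50.0, rel=0.05)

    def test_doubled_leak_halves_resistance(self):
        params = NeuronParams(leak_conductance=40.0)
        r = measure_input_resistance(params, probe_current=-20.0)
        assert r == pytest.approx(25.0, rel=0.05)

    def test_measurement_is_step_size_invariant(self):
        r1 = measure_input_resistance(NeuronParams(), settle_time=400.0, dt=0.025)
        r2 = measure_input_resistance(NeuronParams(), settle_time=400.0, dt=0.0025)
        assert abs(r1 - r2) / r1 < 0.01

    @pytest.mark.parametrize("probe", [0.0, 20.0, -200.0])
    def test_invalid_probes_are_rejected(self, probe):
        with pytest.raises(InvalidProbeError):
            measure_input_resistance(NeuronParams(), probe_current=probe)


class TestSynapse:
    def test_depression_halves_strength_per_event(self):
        params = SynapseParams(depressing=True)
        state = synapse_event(SynapseState(), params)
        assert state.strength == 0.5
        state = synapse_event(state, params)
        assert state.strength == 0.25

    def test_depression_after_k_rapid_spikes_is_exact_power(self):
        params = SynapseParams(depressing=True)
        state = SynapseState()
        for k in range(1, 9):
            state = synapse_event(state, params)
            assert state.strength == 0.5 ** k

    def test_non_depressing_synapse_keeps_full_strength(self):
        params = SynapseParams(depressing=False)
        state = synapse_event(SynapseState(), params)
        assert state.strength == 1.0

    def test_recovery_follows_first_order_kinetics(self):
        """s(t) = 1 - (1 - s0) exp(-t/tau): one tau from 0.5 gives ~0.8161."""
        params = SynapseParams(depressing=True, recovery_tau=1000.0)
        state = SynapseState(strength=0.5)
        state = synapse_step(state, params, 1000.0)
        assert state.strength == pytest.approx(1.0 - 0.5 * np.exp(-1.0), abs=1e-12)
        state = synapse_step(state, params, 1e7)
        assert state.strength == pytest.approx(1.0, abs=1e-9)

    def test_transient_calibration(self):
        """Single event: peak = g_peak within 2%, peak at 2 ms within 10%,
        tail decays with tau = 10 ms within 2%."""
        params = SynapseParams()
        assert measure_peak_conductance(params) == pytest.approx(5.0, rel=0.02)
        assert measure_rise_time(params) == pytest.approx(2.0, rel=0.10)
        assert fit_decay_tau(params) == pytest.approx(10.0, rel=0.02)

    def test_depressed_event_scales_transient(self):
        """An event at strength s produces a transient peaking at s*g_peak."""
        params = SynapseParams(depressing=True)
        state = synapse_event(SynapseState(), params)  # strength now 0.5
        state = SynapseState(strength=state.strength)  # discard first transient
        state = synapse_event(state, params)
        peak, t = 0.0, 0.0
        while t < 8.0:
            state = synapse_step(state, params, 0.01)
            peak = max(peak, synaptic_conductance(state))
            t += 0.01
        assert peak == pytest.approx(2.5, rel=0.02)

    def test_recovery_tau_fit(self):
        assert fit_recovery_tau(SynapseParams()) == pytest.approx(1000.0, rel=0.02)

    def test_synaptic_current_ohmic_arithmetic(self):
        params = SynapseParams(reversal=0.0)
        state = SynapseState(decay_component=5.0, rise_component=0.0)
        assert synaptic_current(state, params, -70.0) == pytest.approx(350.0)
        assert synaptic_current(state, params, 0.0) == 0.0
        assert synaptic_current(SynapseState(), params, -55.0) == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SynapseParams(peak_conductance=-1.0)
        with pytest.raises(ValueError):
            SynapseParams(rise_time=12.0, decay_tau=10.0)
        with pytest.raises(ValueError):
            SynapseParams(depression_factor=0.0)
        with pytest.raises(ValueError):
            SynapseState(strength=0.0)
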