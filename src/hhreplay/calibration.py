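"""Measured (not asserted) model parameters.

Every printed parameter of the model is recoverable as a measurement on
the running implementation: the input resistance from a hyperpolarizing
current step, the synaptic time constants from an exponential fit to a
simulated conductance transient, the depression factor from an event, and
the recovery time constant from a fit to the strength trace.  The CLI's
`calibrate` subcommand and the acceptance script both report these
measurements.
"""

from __future__ import annotations

import numpy as np

from .biophysics import (
    NeuronParams,
    SynapseParams,
    SynapseState,
    measure_input_resistance,
    synapse_event,
    synapse_step,
    synaptic_conductance,
)
from .network import NetworkConfig, build_cyclic_network

__all__ = [
    "synaptic_transient",
    "measure_rise_time",
    "measure_peak_conductance",
    "fit_decay_tau",
    "measure_depression_step",
    "fit_recovery_tau",
    "calibration_report",
]


def synaptic_transient(params: SynapseParams, dt: float = 0.01,
                       t_end: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the conductance after a single event at full strength.

    Returns (t [ms], g [nS]) with t = 0 at the event.
    """
    state = synapse_event(SynapseState(), params)
    n = int(round(t_end / dt))
    g = np.empty(n + 1)
    g[0] = synaptic_conductance(state)
    for k in range(n):
        state = synapse_step(state, params, dt)
        g[k + 1] = synaptic_conductance(state)
    return np.arange(n + 1) * dt, g


def measure_rise_time(params: SynapseParams, dt: float = 0.01) -> float:
    """Time [ms] from presynaptic event to peak conductance."""
    t, g = synaptic_transient(params, dt=dt, t_end=4.0 * params.rise_time)
    return float(t[np.argmax(g)])


def measure_peak_conductance(params: SynapseParams, dt: float = 0.01) -> float:
    """Peak conductance [nS] of a single full-strength event."""
    _, g = synaptic_transient(params, dt=dt, t_end=4.0 * params.rise_time)
    return float(np.max(g))


def fit_decay_tau(params: SynapseParams, dt: float = 0.01) -> float:
    """Exponential time constant [ms] fitted to the conductance tail.

    The fit window starts late enough that the rise component has died
    out, so a straight line in log space recovers the decay constant.
    """
    t0 = params.rise_time + 10.0 * params.rise_tau_const
    t, g = synaptic_transient(params, dt=dt, t_end=t0 + 4.0 * params.decay_tau)
    sel = (t >= t0) & (g > 0)
    slope, _ = np.polyfit(t[sel], np.log(g[sel]), 1)
    return float(-1.0 / slope)


def measure_depression_step(params: SynapseParams) -> float:
    """Strength remaining after one presynaptic event (fraction of baseline)."""
    before = SynapseState()
    after = synapse_event(before, params)
    return after.strength / before.strength


def fit_recovery_tau(params: SynapseParams, dt: float = 1.0,
                     t_end: float = 2000.0) -> float:
    """Time constant [ms] of depression recovery, fitted from the strength trace."""
    state = synapse_event(SynapseState(), params)
    n = int(round(t_end / dt))
    s = np.empty(n + 1)
    s[0] = state.strength
    for k in range(n):
        state = synapse_step(state, params, dt)
        s[k + 1] = state.strength
    t = np.arange(n + 1) * dt
    slope, _ = np.polyfit(t, np.log(1.0 - s + 1e-300), 1)
    return float(-1.0 / slope)


def calibration_report(config: NetworkConfig | None = None) -> dict[str, float]:
    """All calibration measurements on one configuration, as a flat dict."""
    config = config or NetworkConfig()
    syn = config.cortical_synapse
    presyn = build_cyclic_network(config.n_cortical, config.fan_in)
    return {
        "input_resistance_mohm": measure_input_resistance(config.neuron_params),
        "synaptic_decay_tau_ms": fit_decay_tau(syn),
        "synaptic_rise_time_ms": measure_rise_time(syn),
        "peak_conductance_ns": measure_peak_conductance(syn),
        "depression_fraction": measure_depression_step(syn),
        "recovery_tau_ms": fit_recovery_tau(syn),
        "n_cortical": float(len(presyn)),
        "n_lgn_nodes": float(len(config.targets)),
    }
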