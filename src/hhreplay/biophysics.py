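"""Single-compartment Hodgkin-Huxley neuron and conductance synapses.

Units follow cellular-electrophysiology convention throughout the package:
voltage mV, time ms, conductance nS, capacitance pF, current pA,
resistance MOhm (note 1 pA = 1 nS * 1 mV and 1 ms = 1 pF / 1 nS, so the
membrane equation needs no unit conversion factors; clamp resistances in
MOhm convert as g_nS = 1000 / R_MOhm).

The neuron carries Na+, K+ and leak channels,

    C dV/dt = -g_L (V - E_L) - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K) + I,

with Wang-Buzsaki-style gating kinetics.  This choice (rather than the
classic squid rates) keeps the K+ conductance essentially closed at rest,
so the input resistance is set by the leak alone: g_L = 20 nS gives the
calibrated R_in = 50 MOhm, and C = 200 pF gives a 10 ms membrane time
constant.  Spike threshold is near -55 mV.

Synapses are difference-of-exponential conductance transients.  The public
`rise_time` parameter is the time from a presynaptic event to the peak of
the conductance (2 ms by default); the internal rise time constant is
solved from it.  Cortical synapses depress: each presynaptic event scales
a strength variable by `depression_factor` (0.5), which recovers toward 1
with first-order kinetics (tau = 1 s).

Gate integration is exponential Euler (Rush-Larsen); the voltage update is
backward (semi-implicit), which keeps the very stiff voltage-clamp term
used by the replay module unconditionally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import IntegrationError, InvalidProbeError

__all__ = [
    "GatingKinetics",
    "NeuronParams",
    "NeuronState",
    "SynapseParams",
    "SynapseState",
    "step_neuron",
    "resting_state",
    "measure_input_resistance",
    "synapse_event",
    "synapse_step",
    "synaptic_conductance",
    "synaptic_current",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.025  # ms


def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, k * (1.0 + x / (2.0 * k)), safe / (-np.expm1(-safe / k)))
    return out


@dataclass(frozen=True)
class GatingKinetics:
    """Rate-function coefficients for the m, h, n gates.

    Voltages are half/anchor points in mV, rates in 1/ms.  `phi` is the
    temperature-like factor applied to the slow gates (h, n); `v_shift`
    moves every rate function rightward, raising the spike threshold.
    """

    m_alpha_rate: float = 0.1
    m_alpha_vhalf: float = -35.0
    m_alpha_slope: float = 10.0
    m_beta_rate: float = 4.0
    m_beta_vhalf: float = -60.0
    m_beta_tau: float = 18.0
    h_alpha_rate: float = 0.07
    h_alpha_vhalf: float = -58.0
    h_alpha_tau: float = 20.0
    h_beta_vhalf: float = -28.0
    h_beta_slope: float = 10.0
    n_alpha_rate: float = 0.01
    n_alpha_vhalf: float = -34.0
    n_alpha_slope: float = 10.0
    n_beta_rate: float = 0.125
    n_beta_vhalf: float = -44.0
    n_beta_tau: float = 80.0
    phi: float = 1.0
    v_shift: float = 2.0

    def rates(self, V):
        """Return (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n) at V [mV]."""
        u = np.asarray(V, dtype=float) - self.v_shift
        am = self.m_alpha_rate * _vtrap(u - self.m_alpha_vhalf, self.m_alpha_slope)
        bm = self.m_beta_rate * np.exp(-(u - self.m_beta_vhalf) / self.m_beta_tau)
        ah = self.phi * self.h_alpha_rate * np.exp(
            -(u - self.h_alpha_vhalf) / self.h_alpha_tau
        )
        bh = self.phi / (1.0 + np.exp(-(u - self.h_beta_vhalf) / self.h_beta_slope))
        an = self.phi * self.n_alpha_rate * _vtrap(
            u - self.n_alpha_vhalf, self.n_alpha_slope
        )
        bn = self.phi * self.n_beta_rate * np.exp(
            -(u - self.n_beta_vhalf) / self.n_beta_tau
        )
        return am, bm, ah, bh, an, bn

    def steady_state(self, V):
        """Steady-state activations (m_inf, h_inf, n_inf) at V."""
        am, bm, ah, bh, an, bn = self.rates(V)
        return am / (am + bm), ah / (ah + bh), an / (an + bn)


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and channel description of one cortical neuron.

    Defaults are the calibrated reference cell: R_in = 1/g_L = 50 MOhm,
    tau_m = C/g_L = 10 ms.
    """

    capacitance: float = 200.0  # pF
    leak_conductance: float = 20.0  # nS
    leak_reversal: float = -70.0  # mV
    na_max_conductance: float = 7000.0  # nS
    na_reversal: float = 50.0  # mV
    k_max_conductance: float = 1800.0  # nS
    k_reversal: float = -77.0  # mV
    kinetics: GatingKinetics = field(default_factory=GatingKinetics)

    def __post_init__(self):
        if self.capacitance <= 0:
            raise ValueError(f"capacitance must be > 0, got {self.capacitance}")
        for name in ("leak_conductance", "na_max_conductance", "k_max_conductance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous membrane state: voltage and gate activations."""

    V: float  # mV
    m: float
    h: float
    n: float

    def __post_init__(self):
        for g in ("m", "h", "n"):
            val = getattr(self, g)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"gate {g} out of [0, 1]: {val}")


def _advance_gates(m, h, n, V, kin: GatingKinetics, dt: float):
    """Exponential-Euler (Rush-Larsen) gate update with rates frozen at V."""
    am, bm, ah, bh, an, bn = kin.rates(V)
    rm, rh, rn = am + bm, ah + bh, an + bn
    m = am / rm + (m - am / rm) * np.exp(-dt * rm)
    h = ah / rh + (h - ah / rh) * np.exp(-dt * rh)
    n = an / rn + (n - an / rn) * np.exp(-dt * rn)
    return m, h, n


def _implicit_voltage(V, m, h, n, params: NeuronParams, dt: float,
                      extra_g=0.0, extra_gE=0.0, i_ext=0.0):
    """Backward-Euler voltage update; extra_g/extra_gE fold in synapses/clamp.

    All channel terms are linear in V', so

        V' = (C/dt V + sum_i g_i E_i + extra_gE + I_ext) / (C/dt + sum_i g_i + extra_g).
    """
    g_na = params.na_max_conductance * m ** 3 * h
    g_k = params.k_max_conductance * n ** 4
    a = params.capacitance / dt
    num = (a * V
           + params.leak_conductance * params.leak_reversal
           + g_na * params.na_reversal
           + g_k * params.k_reversal
           + extra_gE + i_ext)
    den = a + params.leak_conductance + g_na + g_k + extra_g
    return num / den


def step_neuron(state: NeuronState, params: NeuronParams,
                input_current: float = 0.0, dt: float = DEFAULT_DT) -> NeuronState:
    """Advance one neuron by one time step under an injected current [pA].

    Gates use exponential Euler; the voltage update is backward Euler.
    Raises IntegrationError naming the offending variable if the state
    leaves the finite domain.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    m, h, n = _advance_gates(state.m, state.h, state.n, state.V, params.kinetics, dt)
    V = _implicit_voltage(state.V, m, h, n, params, dt, i_ext=input_current)
    for name, val in (("V", V), ("m", m), ("h", h), ("n", n)):
        if not np.isfinite(val):
            raise IntegrationError(name, time_ms=dt)
    return NeuronState(V=float(V), m=float(m), h=float(h), n=float(n))


def resting_state(params: NeuronParams) -> NeuronState:
    """Steady-state (fixed point) of the membrane equation with zero input."""

    def i_steady(V):
        m, h, n = params.kinetics.steady_state(V)
        return (params.leak_conductance * (params.leak_reversal - V)
                + params.na_max_conductance * m ** 3 * h * (params.na_reversal - V)
                + params.k_max_conductance * n ** 4 * (params.k_reversal - V))

    lo, hi = params.leak_reversal - 15.0, params.leak_reversal + 15.0
    v_rest = brentq(i_steady, lo, hi, xtol=1e-10)
    m, h, n = params.kinetics.steady_state(v_rest)
    return NeuronState(V=float(v_rest), m=float(m), h=float(h), n=float(n))


def measure_input_resistance(params: NeuronParams,
                             probe_current: float = -20.0,
                             settle_time: float = 500.0,
                             dt: float = DEFAULT_DT) -> float:
    """Input resistance [MOhm] from a small hyperpolarizing current step.

    Injects `probe_current` (pA, must be < 0 and |I| <= 50) from rest for
    `settle_time` ms and returns the steady-state deflection divided by the
    probe magnitude.  A spike during the probe invalidates the measurement.
    """
    if probe_current >= 0:
        raise InvalidProbeError(
            f"probe must be hyperpolarizing (I < 0), got {probe_current} pA")
    if abs(probe_current) > 50:
        raise InvalidProbeError(
            f"probe too large for a linear measurement: {probe_current} pA")
    state = resting_state(params)
    v_rest = state.V
    n_steps = int(round(settle_time / dt))
    for k in range(n_steps):
        state = step_neuron(state, params, input_current=probe_current, dt=dt)
        if state.V > -20.0:
            raise InvalidProbeError(
                f"probe evoked a spike at t = {(k + 1) * dt:.3f} ms")
    delta_v = v_rest - state.V  # mV, positive for hyperpolarization
    return 1000.0 * delta_v / abs(probe_current)  # mV/pA -> MOhm


# ---------------------------------------------------------------------------
# Synapse


def _rise_tau_from_peak_time(t_peak: float, decay_tau: float) -> float:
    """Rise time constant of a difference of exponentials with given time-to-peak.

    For g(t) ~ exp(-t/tau_d) - exp(-t/tau_r) the peak sits at
    t_p = tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r), a monotonically
    increasing function of tau_r on (0, tau_d); invert it numerically.
    """

    def f(tau_r):
        return (tau_r * decay_tau / (decay_tau - tau_r)
                * np.log(decay_tau / tau_r) - t_peak)

    return brentq(f, 1e-9 * decay_tau, (1.0 - 1e-9) * decay_tau, xtol=1e-12)


@dataclass(frozen=True)
class SynapseParams:
    """One connection's conductance transient and short-term depression.

    `rise_time` is the time from presynaptic event to peak conductance;
    the transient is normalized so that a single event at full strength
    peaks at exactly `peak_conductance`.
    """

    peak_conductance: float = 5.0  # nS
    rise_time: float = 2.0  # ms, event -> peak
    decay_tau: float = 10.0  # ms
    reversal: float = 0.0  # mV
    depressing: bool = True
    depression_factor: float = 0.5
    recovery_tau: float = 1000.0  # ms

    def __post_init__(self):
        if self.peak_conductance <= 0:
            raise ValueError("peak_conductance must be > 0")
        if not (0.0 < self.depression_factor <= 1.0):
            raise ValueError("depression_factor must be in (0, 1]")
        if not (0.0 < self.rise_time < self.decay_tau):
            raise ValueError("need 0 < rise_time < decay_tau")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be > 0")
        tau_r = _rise_tau_from_peak_time(self.rise_time, self.decay_tau)
        norm = 1.0 / (np.exp(-self.rise_time / self.decay_tau)
                      - np.exp(-self.rise_time / tau_r))
        object.__setattr__(self, "_rise_tau_const", tau_r)
        object.__setattr__(self, "_amp_norm", norm)

    @property
    def rise_tau_const(self) -> float:
        """Internal rise time constant [ms] realizing `rise_time` to peak."""
        return self._rise_tau_const

    @property
    def amp_norm(self) -> float:
        """Event increment per unit strength so the transient peaks at g_peak."""
        return self._amp_norm


@dataclass(frozen=True)
class SynapseState:
    """Conductance-transient components and the depression variable.

    Instantaneous conductance is decay_component - rise_component (>= 0).
    """

    decay_component: float = 0.0
    rise_component: float = 0.0
    strength: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.strength <= 1.0):
            raise ValueError(f"strength out of (0, 1]: {self.strength}")


def synaptic_conductance(state: SynapseState) -> float:
    """Instantaneous conductance [nS]."""
    return max(state.decay_component - state.rise_component, 0.0)


def synapse_event(state: SynapseState, params: SynapseParams) -> SynapseState:
    """Register one presynaptic action potential.

    The transient is incremented so its (isolated) peak equals
    strength * peak_conductance; a depressing synapse then multiplies its
    strength by `depression_factor` (non-depressing synapses, i.e. the LGN
    afferents, keep strength = 1).
    """
    inc = state.strength * params.peak_conductance * params.amp_norm
    new_strength = state.strength * params.depression_factor if params.depressing \
        else state.strength
    return SynapseState(decay_component=state.decay_component + inc,
                        rise_component=state.rise_component + inc,
                        strength=new_strength)


def synapse_step(state: SynapseState, params: SynapseParams,
                 dt: float) -> SynapseState:
    """Advance the transient and depression recovery by dt [ms].

    Components decay with their time constants; strength relaxes to 1 as
    ds/dt = (1 - s) / recovery_tau (integrated exactly).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return SynapseState(
        decay_component=state.decay_component * np.exp(-dt / params.decay_tau),
        rise_component=state.rise_component * np.exp(-dt / params.rise_tau_const),
        strength=1.0 - (1.0 - state.strength) * np.exp(-dt / params.recovery_tau),
    )


def synaptic_current(state: SynapseState, params: SynapseParams,
                     v_post: float) -> float:
    """Postsynaptic current [pA], positive = depolarizing: g (E_rev - V)."""
    return synaptic_conductance(state) * (params.reversal - v_post)
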