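"""Recording network activity and replaying it back into the circuit.

Two replay mechanisms with identical observable outcomes but very
different causal structure:

* **feedforward** — each neuron's membrane voltage is overwritten every
  step with the recorded trace; ongoing inputs are ignored.  Synapses are
  still driven by the (overwritten) spike times, so downstream neurons
  receive the replayed activity.
* **feedback** — an ideal voltage-clamp amplifier per neuron compares the
  membrane voltage with the recorded command voltage and injects
  I_vc = (V_cmd - V_m) / R_s through a small series resistance.  If the
  ongoing activity already matches the command (a *congruent* stimulus),
  the clamp injects nothing while still erasing every alternative
  trajectory — the "counterfactual eraser".

The distinction between the two ways of injecting nothing is captured by
`classify_nothing`: clamp hardware off (Nothing type I) versus clamp on
but silent because activity already matches the command (Nothing type II).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .biophysics import DEFAULT_DT
from .errors import IncompatibleRecordingError, NotApplicableError
from .network import (
    HueStimulus,
    NetworkConfig,
    SimulationResult,
    _simulate,
    network_config_digest,
    run_simulation,
)

__all__ = [
    "ReplayMode",
    "NothingVerdict",
    "Recording",
    "ClampParams",
    "record_reference_run",
    "feedback_clamp_current",
    "run_with_replay",
    "clamp_charge",
    "classify_nothing",
]


class ReplayMode(str, enum.Enum):
    OFF = "off"
    FEEDFORWARD = "feedforward"
    FEEDBACK = "feedback"


class NothingVerdict(str, enum.Enum):
    NOTHING_TYPE_I = "NOTHING_TYPE_I"
    NOTHING_TYPE_II = "NOTHING_TYPE_II"
    INTERVENTION = "INTERVENTION"


@dataclass
class Recording:
    """Per-neuron command-voltage traces plus provenance.

    `v` holds one trace per cortical neuron on the simulation time grid;
    `i_lgn` keeps the LGN synaptic currents of the reference run so replay
    reconstructions can be compared against them.
    """

    v: np.ndarray  # (n, T) mV
    i_lgn: np.ndarray  # (n, T) pA
    spikes: list[np.ndarray]
    dt: float
    duration: float
    stimulus: HueStimulus
    seed: int
    config_digest: str
    labels: list[str]

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]


@dataclass(frozen=True)
class ClampParams:
    """Feedback voltage-clamp settings.

    The series resistance sets the correction speed: the clamp time
    constant R_s * C must stay well below the membrane time constant and,
    for accuracy of the implicit solve, within 10x the integration step.
    """

    series_resistance: float = 0.05  # MOhm
    enabled: bool = True

    def __post_init__(self):
        if self.series_resistance <= 0:
            raise ValueError("series_resistance must be > 0")

    def conductance(self) -> float:
        """Clamp conductance in nS (1000 / R_s[MOhm])."""
        return 1000.0 / self.series_resistance


def feedback_clamp_current(v_cmd: float, v_m: float,
                           series_resistance: float) -> float:
    """Ideal-amplifier clamp current [pA], positive = depolarizing.

    I_vc = (V_cmd - V_m) / R_s; inside the integration loop the same term
    enters the semi-implicit voltage update, so arbitrarily stiff clamps
    remain stable.
    """
    if series_resistance <= 0:
        raise ValueError("series_resistance must be > 0")
    return 1000.0 * (np.asarray(v_cmd, dtype=float) - v_m) / series_resistance


def record_reference_run(config: NetworkConfig, stimulus: HueStimulus,
                         duration: float = 500.0, dt: float = DEFAULT_DT,
                         seed: int = 0) -> Recording:
    """Run the circuit open loop and store its voltage traces as a Recording.

    The stored traces equal `run_simulation`'s bit for bit.
    """
    result = run_simulation(config, stimulus, duration=duration, dt=dt, seed=seed)
    return Recording(v=result.v.copy(), i_lgn=result.i_lgn.copy(),
                     spikes=[s.copy() for s in result.spikes],
                     dt=dt, duration=duration, stimulus=stimulus, seed=int(seed),
                     config_digest=result.config_digest, labels=result.labels)


def run_with_replay(config: NetworkConfig, stimulus: HueStimulus,
                    recording: Recording | None, mode: ReplayMode | str,
                    clamp: ClampParams | None = None,
                    seed: int = 0) -> SimulationResult:
    """Run the circuit while replaying a Recording into the cortical neurons.

    mode "off" reproduces `run_simulation` exactly (the clamp hardware is
    absent); "feedforward" overwrites each neuron's voltage with the
    recording; "feedback" adds the voltage-clamp current toward the
    recorded command voltage.  The recording's grid must match the run.
    """
    mode = ReplayMode(mode)
    if mode is ReplayMode.OFF:
        return _simulate(config, stimulus, duration=recording.duration
                         if recording is not None else 500.0,
                         dt=recording.dt if recording is not None else DEFAULT_DT,
                         seed=seed, mode="off")
    if recording is None:
        raise IncompatibleRecordingError(f"mode {mode.value} requires a recording")
    if recording.n_neurons != config.n_cortical:
        raise IncompatibleRecordingError(
            f"recording has {recording.n_neurons} neurons, "
            f"config has {config.n_cortical}")
    expected_T = int(round(recording.duration / recording.dt)) + 1
    if recording.v.shape[1] != expected_T:
        raise IncompatibleRecordingError(
            f"recording grid ({recording.v.shape[1]} samples) inconsistent "
            f"with dt={recording.dt} and duration={recording.duration}")
    if recording.config_digest != network_config_digest(config):
        # replay across configs is legitimate (e.g. rewired networks); grid
        # compatibility is what matters, so only sanity-checked above.
        pass
    g_c = 0.0
    if mode is ReplayMode.FEEDBACK:
        clamp = clamp or ClampParams()
        tau_clamp = clamp.series_resistance * config.neuron_params.capacitance / 1000.0
        if tau_clamp > 10.0 * recording.dt:
            raise ValueError(
                f"clamp time constant {tau_clamp:.3g} ms exceeds 10*dt; "
                "decrease series_resistance or the step size")
        g_c = clamp.conductance()
    return _simulate(config, stimulus, duration=recording.duration,
                     dt=recording.dt, seed=seed, mode=mode.value,
                     command_v=recording.v, clamp_conductance=g_c)


def clamp_charge(result: SimulationResult) -> np.ndarray:
    """Per-neuron total clamp charge [pC], the integral of |I_vc| over time.

    Undefined for feedforward replay, where no clamp current exists.
    """
    if result.mode == ReplayMode.FEEDFORWARD.value:
        raise NotApplicableError(
            "clamp charge is undefined for feedforward replay (no clamp current)")
    return np.trapezoid(np.abs(result.i_vc), dx=result.dt, axis=1) / 1000.0


def classify_nothing(mode: ReplayMode | str, clamp_enabled: bool,
                     i_vc: np.ndarray, tolerance: float = 1.0) -> NothingVerdict:
    """Classify a replay run's intervention status.

    Nothing type I: the clamp hardware is off — nothing is injected and
    nothing could be.  Nothing type II: the clamp is armed but silent
    (max |I_vc| <= tolerance on every neuron) because ongoing activity
    already matches the command; counterfactuals are erased regardless.
    Anything else — including feedforward replay, which overwrites the
    voltage every step — is an intervention.
    """
    mode = ReplayMode(mode)
    if mode is ReplayMode.FEEDFORWARD:
        return NothingVerdict.INTERVENTION
    if mode is ReplayMode.OFF or not clamp_enabled:
        return NothingVerdict.NOTHING_TYPE_I
    if np.max(np.abs(i_vc)) <= tolerance:
        return NothingVerdict.NOTHING_TYPE_II
    return NothingVerdict.INTERVENTION
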