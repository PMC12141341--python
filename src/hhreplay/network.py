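"""Five-neuron cyclic cortical network with LGN drive and hue encoding.

The reference circuit is the toy visual system used throughout the
package: `n_cortical` identical HH neurons (labelled a, b, c, ...) where
neuron k receives a depressing synapse from each of the `fan_in`
immediately preceding neurons in cyclic order, plus two LGN input nodes
firing Poisson-with-refractory spike trains through non-depressing
synapses onto neurons a and b.  The hue of the stimulus selects which LGN
nodes are active: green turns on both, red only the node driving b, blue
only the node driving a.  With the calibrated parameters this yields the
"hue computation": green ignites the whole network, red/blue drive only
the directly targeted neuron.

LGN spike trains are a pure function of (run seed, node id) and do not
depend on the hue, so a node active under two different hues emits the
identical train — the congruence contract the replay experiments rely on.

The same integration loop serves open-loop runs and both replay modes
(see `replay`): voltage is updated semi-implicitly so the stiff clamp
conductance is unconditionally stable, and synapses are driven by spikes
detected on each presynaptic voltage (recorded, clamped or free alike).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import biophysics as bp
from .biophysics import DEFAULT_DT, NeuronParams, SynapseParams
from .errors import IntegrationError, InvalidStimulusError, InvalidTopologyError

__all__ = [
    "HUES",
    "SPIKE_THRESHOLD",
    "SPIKE_MIN_SEPARATION",
    "HueStimulus",
    "LGNParams",
    "NetworkConfig",
    "SimulationResult",
    "neuron_labels",
    "build_cyclic_network",
    "hue_to_lgn",
    "generate_lgn_spike_train",
    "detect_spikes",
    "run_simulation",
    "network_config_digest",
]

HUES = ("green", "red", "blue", "none")
SPIKE_THRESHOLD = 0.0  # mV, upward crossing defines a spike
SPIKE_MIN_SEPARATION = 2.0  # ms, refractory rule for event detection


def neuron_labels(n: int) -> list[str]:
    """Cortical neuron labels a, b, c, ..."""
    return [chr(ord("a") + i) for i in range(n)]


@dataclass(frozen=True)
class HueStimulus:
    """A single light presentation: which hue, when, and for how long."""

    hue: str = "green"
    onset: float = 100.0  # ms
    duration: float = 300.0  # ms

    def __post_init__(self):
        if self.hue not in HUES:
            raise InvalidStimulusError(
                f"unknown hue {self.hue!r}; expected one of {HUES}")
        if self.onset < 0 or self.duration < 0:
            raise ValueError("onset and duration must be >= 0")


@dataclass(frozen=True)
class LGNParams:
    """Statistics of one LGN node's spike train while its channel is active.

    `rate` is the effective rate (spikes/s): inter-spike intervals are
    refractory + Exp(1/rate - refractory), so the mean interval is 1/rate.
    """

    rate: float = 150.0  # spikes/s
    refractory: float = 2.0  # ms

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.rate * self.refractory >= 1000.0:
            raise ValueError("rate is unreachable with this refractory period")


def build_cyclic_network(n_cortical: int, fan_in: int) -> dict[int, tuple[int, ...]]:
    """Presynaptic sets of the cyclic circuit.

    Neuron k receives from neurons (k-1, k-2, ..., k-fan_in) mod n;
    e.g. with (5, 3), neuron d <- {a, b, c} and neuron a <- {c, d, e}.
    """
    if not (0 < fan_in < n_cortical):
        raise InvalidTopologyError(
            f"need 0 < fan_in < n_cortical, got fan_in={fan_in}, "
            f"n_cortical={n_cortical}")
    return {
        k: tuple(sorted((k - j) % n_cortical for j in range(1, fan_in + 1)))
        for k in range(n_cortical)
    }


@dataclass(frozen=True)
class NetworkConfig:
    """Full description of the circuit (topology, cell, synapses, inputs)."""

    n_cortical: int = 5
    fan_in: int = 3
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    cortical_synapse: SynapseParams = field(
        default_factory=lambda: SynapseParams(depressing=True))
    lgn_synapse: SynapseParams = field(
        default_factory=lambda: SynapseParams(depressing=False))
    lgn_params: LGNParams = field(default_factory=LGNParams)
    # LGN node id -> index of the cortical neuron it innervates
    lgn_targets: tuple[tuple[int, int], ...] = ((0, 0), (1, 1))
    synaptic_delay: float = 1.0  # ms

    def __post_init__(self):
        build_cyclic_network(self.n_cortical, self.fan_in)  # validates topology
        targets = dict(self.lgn_targets)
        values = list(targets.values())
        if len(set(values)) != len(values):
            raise InvalidTopologyError("lgn_targets must be injective")
        if any(not (0 <= v < self.n_cortical) for v in values):
            raise InvalidTopologyError("lgn_targets out of cortical range")
        if self.synaptic_delay <= 0:
            raise ValueError("synaptic_delay must be > 0")

    @property
    def targets(self) -> dict[int, int]:
        return dict(self.lgn_targets)

    @property
    def labels(self) -> list[str]:
        return neuron_labels(self.n_cortical)


def network_config_digest(config: NetworkConfig) -> str:
    """Stable hash of the full configuration, for provenance tracking."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=repr)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def hue_to_lgn(hue: str, lgn_targets=((0, 0), (1, 1))) -> frozenset[int]:
    """Which LGN nodes a hue activates.

    Green activates every node; red only the node innervating neuron b
    (index 1); blue only the node innervating neuron a (index 0); none
    activates nothing.
    """
    targets = dict(lgn_targets)
    if hue == "green":
        return frozenset(targets)
    if hue == "red":
        return frozenset(node for node, tgt in targets.items() if tgt == 1)
    if hue == "blue":
        return frozenset(node for node, tgt in targets.items() if tgt == 0)
    if hue == "none":
        return frozenset()
    raise InvalidStimulusError(f"unknown hue {hue!r}; expected one of {HUES}")


def generate_lgn_spike_train(params: LGNParams, node_id: int, run_seed: int,
                             window: tuple[float, float]) -> np.ndarray:
    """Seeded Poisson-with-refractory spike times [ms] inside the window.

    The stream is a pure function of (run_seed, node_id): the hue decides
    only whether a node is used, never what it would have fired, so runs
    under different hues share the trains of their common active nodes.
    """
    onset, duration = window
    if duration < 0:
        raise ValueError("window duration must be >= 0")
    if duration == 0:
        return np.empty(0)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(run_seed), spawn_key=(int(node_id),)))
    scale = 1000.0 / params.rate - params.refractory  # ms, exponential part
    end = onset + duration
    times = []
    t = onset + rng.exponential(scale)
    while t < end:
        times.append(t)
        t += params.refractory + rng.exponential(scale)
    return np.asarray(times)


def detect_spikes(trace: np.ndarray, dt: float,
                  threshold: float = SPIKE_THRESHOLD,
                  min_separation: float = SPIKE_MIN_SEPARATION) -> np.ndarray:
    """Spike times [ms] as upward threshold crossings with a refractory rule."""
    trace = np.asarray(trace, dtype=float)
    cross = np.nonzero((trace[:-1] < threshold) & (trace[1:] >= threshold))[0] + 1
    if cross.size == 0:
        return np.empty(0)
    keep = [cross[0]]
    min_steps = int(round(min_separation / dt))
    for idx in cross[1:]:
        if idx - keep[-1] >= min_steps:
            keep.append(idx)
    return np.asarray(keep, dtype=float) * dt


@dataclass
class SimulationResult:
    """Traces and spikes of one run on a common time grid.

    `i_vc` is identically zero unless the run used feedback replay;
    `i_lgn` is each neuron's total synaptic current from LGN afferents.
    """

    times: np.ndarray  # (T,) ms
    v: np.ndarray  # (n, T) mV
    i_lgn: np.ndarray  # (n, T) pA
    i_vc: np.ndarray  # (n, T) pA
    spikes: list[np.ndarray]  # per neuron, ms
    dt: float
    duration: float
    seed: int
    stimulus: HueStimulus
    mode: str  # "off" | "feedforward" | "feedback"
    config_digest: str
    labels: list[str]

    def spike_counts(self) -> np.ndarray:
        return np.array([s.size for s in self.spikes])

    def firing_count(self) -> int:
        """Number of cortical neurons that fired at least once."""
        return int(np.count_nonzero(self.spike_counts() > 0))


def _simulate(config: NetworkConfig, stimulus: HueStimulus, duration: float,
              dt: float, seed: int, mode: str = "off",
              command_v: np.ndarray | None = None,
              clamp_conductance: float = 0.0) -> SimulationResult:
    """Shared integration loop for open-loop runs and both replay modes.

    `command_v` (n, T) is required for the replay modes.  In feedback mode
    the clamp drives toward the command value at the *end* of each step
    (the target of the backward-Euler update), so a run whose free
    dynamics already match the command draws zero clamp current up to
    floating-point noise.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < stimulus.onset + stimulus.duration:
        raise ValueError("duration must cover the stimulus window")
    n = config.n_cortical
    T = int(round(duration / dt)) + 1
    times = np.arange(T) * dt

    presyn = build_cyclic_network(n, config.fan_in)
    edges = [(pre, post) for post in range(n) for pre in presyn[post]]
    n_edges = len(edges)
    w_cort = np.zeros((n, n_edges))
    out_edges: list[list[int]] = [[] for _ in range(n)]
    for e, (pre, post) in enumerate(edges):
        w_cort[post, e] = 1.0
        out_edges[pre].append(e)

    targets = config.targets
    lgn_nodes = sorted(targets)
    w_lgn = np.zeros((n, len(lgn_nodes)))
    for j, node in enumerate(lgn_nodes):
        w_lgn[targets[node], j] = 1.0

    delay_steps = max(1, int(round(config.synaptic_delay / dt)))
    cort_events: list[list[int]] = [[] for _ in range(T)]
    lgn_events: list[list[int]] = [[] for _ in range(T)]
    for j, node in enumerate(lgn_nodes):
        if node not in hue_to_lgn(stimulus.hue, config.lgn_targets):
            continue
        train = generate_lgn_spike_train(
            config.lgn_params, node, seed, (stimulus.onset, stimulus.duration))
        for t_spk in train:
            step = int(round(t_spk / dt)) + delay_steps
            if step < T:
                lgn_events[step].append(j)

    params = config.neuron_params
    kin = params.kinetics
    rest = bp.resting_state(params)
    V = np.full(n, rest.V)
    m = np.full(n, rest.m)
    h = np.full(n, rest.h)
    ng = np.full(n, rest.n)

    syn_c, syn_l = config.cortical_synapse, config.lgn_synapse
    cd = np.zeros(n_edges)  # decay components, cortical
    cr = np.zeros(n_edges)  # rise components
    s = np.ones(n_edges)  # depression strengths
    ld = np.zeros(len(lgn_nodes))
    lr = np.zeros(len(lgn_nodes))
    ls = np.ones(len(lgn_nodes))
    f_cd = np.exp(-dt / syn_c.decay_tau)
    f_cr = np.exp(-dt / syn_c.rise_tau_const)
    f_rec = np.exp(-dt / syn_c.recovery_tau)
    f_ld = np.exp(-dt / syn_l.decay_tau)
    f_lr = np.exp(-dt / syn_l.rise_tau_const)
    amp_c = syn_c.peak_conductance * syn_c.amp_norm
    amp_l = syn_l.peak_conductance * syn_l.amp_norm

    feedback = mode == "feedback"
    feedforward = mode == "feedforward"
    if (feedback or feedforward) and command_v is None:
        raise ValueError(f"mode {mode!r} requires a command-voltage array")
    g_c = clamp_conductance  # nS

    v_out = np.empty((n, T))
    i_lgn_out = np.zeros((n, T))
    i_vc_out = np.zeros((n, T))
    v_out[:, 0] = command_v[:, 0] if feedforward else V
    V = v_out[:, 0].copy()

    min_sep_steps = int(round(SPIKE_MIN_SEPARATION / dt))
    last_spike = np.full(n, -10 * min_sep_steps)
    spikes: list[list[float]] = [[] for _ in range(n)]
    labels = config.labels

    for k in range(T - 1):
        j = k + 1
        # synaptic transients decay; depression recovers toward 1
        cd *= f_cd
        cr *= f_cr
        s = 1.0 - (1.0 - s) * f_rec
        ld *= f_ld
        lr *= f_lr
        for e in cort_events[j]:
            inc = s[e] * amp_c
            cd[e] += inc
            cr[e] += inc
            if syn_c.depressing:
                s[e] *= syn_c.depression_factor
        for e in lgn_events[j]:
            inc = ls[e] * amp_l
            ld[e] += inc
            lr[e] += inc
            if syn_l.depressing:
                ls[e] *= syn_l.depression_factor
        g_cort = w_cort @ (cd - cr)
        g_lgn = w_lgn @ (ld - lr)

        m, h, ng = bp._advance_gates(m, h, ng, V, kin, dt)

        if feedforward:
            V_new = command_v[:, j]
        else:
            extra_g = g_cort + g_lgn
            extra_gE = g_cort * syn_c.reversal + g_lgn * syn_l.reversal
            if feedback:
                extra_g = extra_g + g_c
                extra_gE = extra_gE + g_c * command_v[:, j]
            V_new = bp._implicit_voltage(V, m, h, ng, params, dt,
                                         extra_g=extra_g, extra_gE=extra_gE)
            if not np.all(np.isfinite(V_new)):
                bad = int(np.nonzero(~np.isfinite(V_new))[0][0])
                raise IntegrationError("V", j * dt, neuron=labels[bad])
        v_out[:, j] = V_new
        i_lgn_out[:, j] = g_lgn * (syn_l.reversal - V_new)
        if feedback:
            i_vc_out[:, j] = g_c * (command_v[:, j] - V_new)

        crossed = (V < SPIKE_THRESHOLD) & (V_new >= SPIKE_THRESHOLD)
        if crossed.any():
            for i in np.nonzero(crossed)[0]:
                if j - last_spike[i] >= min_sep_steps:
                    last_spike[i] = j
                    spikes[i].append(j * dt)
                    tgt = j + delay_steps
                    if tgt < T:
                        cort_events[tgt].extend(out_edges[i])
        V = V_new.copy() if feedforward else V_new

    return SimulationResult(
        times=times, v=v_out, i_lgn=i_lgn_out, i_vc=i_vc_out,
        spikes=[np.asarray(sp) for sp in spikes], dt=dt, duration=duration,
        seed=int(seed), stimulus=stimulus, mode=mode,
        config_digest=network_config_digest(config), labels=labels)


def run_simulation(config: NetworkConfig, stimulus: HueStimulus,
                   duration: float = 500.0, dt: float = DEFAULT_DT,
                   seed: int = 0) -> SimulationResult:
    """Open-loop run of the circuit under a hue stimulus.

    Deterministic given (config, stimulus, seed, dt): repeated calls
    produce bitwise-identical traces.
    """
    return _simulate(config, stimulus, duration, dt, seed, mode="off")
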