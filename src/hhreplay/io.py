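"""Configuration documents and trace serialization.

A run is fully described by a single human-editable YAML document whose
defaults are the reference profile: every default is either a printed
model parameter (five neurons, fan-in three, g_syn = 5 nS, tau_syn =
10 ms, 2 ms rise, depression to 50% with 1 s recovery, R_in = 50 MOhm)
or a documented calibration decision (kinetics shift, LGN rate, clamp
series resistance, timing).  Unknown keys are rejected and every loaded
config carries a content digest so outputs are reproducible from
(digest, seed) alone.

Traces serialize to a long-format CSV (time_ms, neuron, v_mV, i_vc_pA,
i_lgn_pA) plus a JSON sidecar holding dt, seeds, spike times, the config
digest and the replay mode; the round trip is bit-exact.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biophysics import GatingKinetics, NeuronParams, SynapseParams
from .errors import ConfigError, TraceFormatError
from .network import HueStimulus, LGNParams, NetworkConfig, SimulationResult
from .replay import ClampParams, Recording

__all__ = [
    "RunConfig",
    "default_config_dict",
    "load_config",
    "save_config",
    "write_traces",
    "read_traces",
    "write_recording",
    "read_recording",
]

# Reference profile: printed parameters plus calibration decisions.
_DEFAULTS: dict = {
    "network": {
        "n_cortical": 5,
        "fan_in": 3,
        "synaptic_delay_ms": 1.0,
        "lgn": {
            "rate_hz": 150.0,
            "refractory_ms": 2.0,
            "targets": {0: 0, 1: 1},  # node -> cortical neuron index
        },
    },
    "neuron": {
        "capacitance_pf": 200.0,
        "leak_conductance_ns": 20.0,
        "leak_reversal_mv": -70.0,
        "na_max_conductance_ns": 7000.0,
        "na_reversal_mv": 50.0,
        "k_max_conductance_ns": 1800.0,
        "k_reversal_mv": -77.0,
        "v_shift_mv": 2.0,
        "phi": 1.0,
    },
    "cortical_synapse": {
        "peak_conductance_ns": 5.0,
        "rise_time_ms": 2.0,
        "decay_tau_ms": 10.0,
        "reversal_mv": 0.0,
        "depressing": True,
        "depression_factor": 0.5,
        "recovery_tau_ms": 1000.0,
    },
    "lgn_synapse": {
        "peak_conductance_ns": 5.0,
        "rise_time_ms": 2.0,
        "decay_tau_ms": 10.0,
        "reversal_mv": 0.0,
        "depressing": False,
        "depression_factor": 0.5,
        "recovery_tau_ms": 1000.0,
    },
    "clamp": {
        "series_resistance_mohm": 0.05,
        "enabled": True,
    },
    "timing": {
        "onset_ms": 100.0,
        "stimulus_ms": 300.0,
        "total_ms": 500.0,
        "dt_ms": 0.025,
    },
    "seed": 0,
    "outdir": "runs",
}


def default_config_dict() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and key != "targets":
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


@dataclass(frozen=True)
class RunConfig:
    """A validated configuration plus its provenance digest."""

    network: NetworkConfig
    clamp: ClampParams
    onset: float
    stimulus_duration: float
    total_duration: float
    dt: float
    seed: int
    outdir: str
    digest: str
    raw: dict = field(repr=False)

    def stimulus(self, hue: str) -> HueStimulus:
        dur = 0.0 if hue == "none" else self.stimulus_duration
        return HueStimulus(hue=hue, onset=self.onset, duration=dur)


def _build(doc: dict) -> RunConfig:
    def section(name):
        return doc[name]

    try:
        neu = section("neuron")
        neuron = NeuronParams(
            capacitance=float(neu["capacitance_pf"]),
            leak_conductance=float(neu["leak_conductance_ns"]),
            leak_reversal=float(neu["leak_reversal_mv"]),
            na_max_conductance=float(neu["na_max_conductance_ns"]),
            na_reversal=float(neu["na_reversal_mv"]),
            k_max_conductance=float(neu["k_max_conductance_ns"]),
            k_reversal=float(neu["k_reversal_mv"]),
            kinetics=GatingKinetics(v_shift=float(neu["v_shift_mv"]),
                                    phi=float(neu["phi"])),
        )

        def synapse(sec):
            return SynapseParams(
                peak_conductance=float(sec["peak_conductance_ns"]),
                rise_time=float(sec["rise_time_ms"]),
                decay_tau=float(sec["decay_tau_ms"]),
                reversal=float(sec["reversal_mv"]),
                depressing=bool(sec["depressing"]),
                depression_factor=float(sec["depression_factor"]),
                recovery_tau=float(sec["recovery_tau_ms"]),
            )

        net = section("network")
        targets = tuple(sorted((int(k), int(v))
                               for k, v in net["lgn"]["targets"].items()))
        network = NetworkConfig(
            n_cortical=int(net["n_cortical"]),
            fan_in=int(net["fan_in"]),
            neuron_params=neuron,
            cortical_synapse=synapse(section("cortical_synapse")),
            lgn_synapse=synapse(section("lgn_synapse")),
            lgn_params=LGNParams(rate=float(net["lgn"]["rate_hz"]),
                                 refractory=float(net["lgn"]["refractory_ms"])),
            lgn_targets=targets,
            synaptic_delay=float(net["synaptic_delay_ms"]),
        )
        clamp = ClampParams(
            series_resistance=float(section("clamp")["series_resistance_mohm"]),
            enabled=bool(section("clamp")["enabled"]),
        )
        timing = section("timing")
        onset = float(timing["onset_ms"])
        stim = float(timing["stimulus_ms"])
        total = float(timing["total_ms"])
        dt = float(timing["dt_ms"])
        if dt <= 0:
            raise ValueError("timing.dt_ms must be > 0")
        if total < onset + stim:
            raise ValueError("timing.total_ms must cover onset + stimulus")
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc

    canon = json.dumps(doc, sort_keys=True, default=str)
    digest = hashlib.sha256(canon.encode()).hexdigest()[:16]
    return RunConfig(network=network, clamp=clamp, onset=onset,
                     stimulus_duration=stim, total_duration=total, dt=dt,
                     seed=int(doc["seed"]), outdir=str(doc["outdir"]),
                     digest=digest, raw=doc)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; None or an empty file gives defaults."""
    if path is None:
        user = {}
    else:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config document must be a mapping")
    doc = _merge(_DEFAULTS, user)
    if "targets" in (user.get("network", {}) or {}).get("lgn", {}):
        doc["network"]["lgn"]["targets"] = {
            int(k): int(v)
            for k, v in user["network"]["lgn"]["targets"].items()}
    return _build(doc)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-merged document; a reload yields the same digest."""
    Path(path).write_text(yaml.safe_dump(config.raw, sort_keys=True))


# ---------------------------------------------------------------------------
# Trace files


def _sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_traces(result: SimulationResult, path: str | Path) -> None:
    """Serialize a SimulationResult to `<path>` (CSV) + `<path>.json` sidecar."""
    n, T = result.v.shape
    frame = pd.DataFrame({
        "time_ms": np.tile(result.times, n),
        "neuron": np.repeat(result.labels, T),
        "v_mV": result.v.ravel(),
        "i_vc_pA": result.i_vc.ravel(),
        "i_lgn_pA": result.i_lgn.ravel(),
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "dt_ms": result.dt,
        "duration_ms": result.duration,
        "seed": result.seed,
        "mode": result.mode,
        "config_digest": result.config_digest,
        "stimulus": {"hue": result.stimulus.hue, "onset_ms": result.stimulus.onset,
                     "duration_ms": result.stimulus.duration},
        "labels": list(result.labels),
        "n_samples": int(T),
        "spike_times_ms": {lab: list(map(float, sp))
                           for lab, sp in zip(result.labels, result.spikes)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_traces(path: str | Path) -> SimulationResult:
    """Read back a trace CSV + sidecar pair, checking their consistency."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceFormatError(f"cannot parse trace CSV {path}: {exc}") from exc
    required = {"time_ms", "neuron", "v_mV", "i_vc_pA", "i_lgn_pA"}
    if not required.issubset(frame.columns):
        raise TraceFormatError(
            f"trace CSV {path} lacks columns {sorted(required - set(frame.columns))}")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise TraceFormatError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    labels = list(meta["labels"])
    T = int(meta["n_samples"])
    if len(frame) != len(labels) * T:
        raise TraceFormatError(
            f"trace CSV has {len(frame)} rows but sidecar promises "
            f"{len(labels)} neurons x {T} samples (line {len(frame) + 2})")
    by_label = {lab: grp for lab, grp in frame.groupby("neuron", sort=False)}
    if set(by_label) != set(labels):
        raise TraceFormatError(
            f"neuron set mismatch: CSV has {sorted(by_label)}, "
            f"sidecar has {sorted(labels)}")
    v = np.vstack([by_label[lab]["v_mV"].to_numpy() for lab in labels])
    i_vc = np.vstack([by_label[lab]["i_vc_pA"].to_numpy() for lab in labels])
    i_lgn = np.vstack([by_label[lab]["i_lgn_pA"].to_numpy() for lab in labels])
    times = by_label[labels[0]]["time_ms"].to_numpy()
    stim = meta["stimulus"]
    return SimulationResult(
        times=times, v=v, i_lgn=i_lgn, i_vc=i_vc,
        spikes=[np.asarray(meta["spike_times_ms"][lab]) for lab in labels],
        dt=float(meta["dt_ms"]), duration=float(meta["duration_ms"]),
        seed=int(meta["seed"]),
        stimulus=HueStimulus(hue=stim["hue"], onset=stim["onset_ms"],
                             duration=stim["duration_ms"]),
        mode=meta["mode"], config_digest=meta["config_digest"], labels=labels)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Serialize a Recording in the same CSV + sidecar dialect."""
    n, T = recording.v.shape
    frame = pd.DataFrame({
        "time_ms": np.tile(np.arange(T) * recording.dt, n),
        "neuron": np.repeat(recording.labels, T),
        "v_mV": recording.v.ravel(),
        "i_lgn_pA": recording.i_lgn.ravel(),
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "dt_ms": recording.dt,
        "duration_ms": recording.duration,
        "seed": recording.seed,
        "config_digest": recording.config_digest,
        "stimulus": {"hue": recording.stimulus.hue,
                     "onset_ms": recording.stimulus.onset,
                     "duration_ms": recording.stimulus.duration},
        "labels": list(recording.labels),
        "n_samples": int(T),
        "spike_times_ms": {lab: list(map(float, sp))
                           for lab, sp in zip(recording.labels, recording.spikes)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_recording(path: str | Path) -> Recording:
    """Load a Recording written by `write_recording`."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceFormatError(f"cannot parse recording CSV {path}: {exc}") from exc
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise TraceFormatError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    labels = list(meta["labels"])
    T = int(meta["n_samples"])
    if len(frame) != len(labels) * T:
        raise TraceFormatError(
            f"recording CSV has {len(frame)} rows, expected {len(labels) * T}")
    by_label = {lab: grp for lab, grp in frame.groupby("neuron", sort=False)}
    if set(by_label) != set(labels):
        raise TraceFormatError("neuron set mismatch between CSV and sidecar")
    stim = meta["stimulus"]
    return Recording(
        v=np.vstack([by_label[lab]["v_mV"].to_numpy() for lab in labels]),
        i_lgn=np.vstack([by_label[lab]["i_lgn_pA"].to_numpy() for lab in labels]),
        spikes=[np.asarray(meta["spike_times_ms"][lab]) for lab in labels],
        dt=float(meta["dt_ms"]), duration=float(meta["duration_ms"]),
        stimulus=HueStimulus(hue=stim["hue"], onset=stim["onset_ms"],
                             duration=stim["duration_ms"]),
        seed=int(meta["seed"]), config_digest=meta["config_digest"],
        labels=labels)
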