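# hhreplay

A self-contained "artificial subject": a five-neuron Hodgkin–Huxley visual
cortex that performs a toy hue computation, together with the apparatus to
**record** its activity and **replay** it back into the very same neurons —
either by brute-force voltage overwrite (feedforward replay) or through a
per-neuron feedback voltage clamp that injects current only when activity
deviates from the recording (a *counterfactual eraser*). A discrete
Turing-machine analogue makes the computational content of the two replay
modes exact.

The package is aimed at computational neuroscientists and philosophers of
mind who want a runnable, quantitative version of record-and-replay thought
experiments: every claim about the replay ("the clamp injects nothing under
a congruent stimulus", "the feedback replay recreates exactly the missing
input") is a measurement on simulated traces, not an illustration.

## The model

Each cortical neuron is a single compartment,

```
C dV/dt = −g_L (V−E_L) − g_Na m³h (V−E_Na) − g_K n⁴ (V−E_K) + I_syn + I_vc
```

with Wang–Buzsáki-style gating kinetics calibrated so that the input
resistance is R_in = 50 MΩ and the spike threshold sits near −55 mV
(C = 200 pF, g_L = 20 nS, τ_m = 10 ms). Five identical neurons *a…e* are
wired in cyclic order, each receiving from its three predecessors through
excitatory synapses (g_syn = 5 nS, rise to peak 2 ms, decay τ_syn = 10 ms)
with short-term depression: each presynaptic spike halves the synaptic
strength, which recovers with τ = 1 s. Two LGN input nodes fire seeded
Poisson trains (150 s⁻¹, 2 ms refractory) onto neurons *a* and *b* through
non-depressing synapses. Green light activates both nodes and ignites the
whole network; red or blue activates a single node and drives only its
target neuron — the "hue computation".

The feedback replay attaches an ideal voltage-clamp amplifier to every
neuron: `I_vc = (V_cmd − V_m)/R_s` with a stiff series resistance
(R_s = 0.05 MΩ), solved implicitly so the clamp is unconditionally stable.
Because LGN streams are pure functions of (seed, node), a replay can be
made exactly *congruent* (same hue, same seed) or *incongruent* with the
ongoing stimulus.

## Worked example

```python
import numpy as np
from hhreplay import (NetworkConfig, HueStimulus, ClampParams, ReplayMode,
                      record_reference_run, run_with_replay, classify_nothing)

config = NetworkConfig()
green = HueStimulus(hue="green", onset=100.0, duration=300.0)
red = HueStimulus(hue="red", onset=100.0, duration=300.0)

recording = record_reference_run(config, green, seed=7)
print({lab: len(s) for lab, s in zip(recording.labels, recording.spikes)})

replay = run_with_replay(config, red, recording, ReplayMode.FEEDBACK,
                         ClampParams(), seed=7)
print(replay.firing_count(), np.max(np.abs(replay.i_vc[0])),
      np.max(np.abs(replay.i_vc[1])))
```

prints

```
{'a': 12, 'b': 17, 'c': 2, 'd': 2, 'e': 1}
5 931.2  4.3e-10
```

Under the green stimulus all five neurons fire (the recording). Replaying
that recording while showing **red** light restores the full green firing
pattern: the clamp injects up to ~931 pA into neuron *a* — reconstructing
the LGN input the red stimulus withholds — while injecting nothing
(≤ 10⁻⁹ pA) into neuron *b*, whose input is already present. Repeating the
replay under the matching **green** stimulus with the same seed yields
`max |I_vc| ≈ 6e-10 pA` on every neuron: the clamp does nothing at all, yet
every alternative activity pattern is erased (`classify_nothing` reports
`NOTHING_TYPE_II`, versus `NOTHING_TYPE_I` when the amplifier is simply
switched off).

The same distinction, discretely: `hhreplay tm-demo` records a Turing
machine's head operations (s, t, w, m) and replays them; feedback replay on
the recorded tape makes zero interventions, on any other tape it forces the
recorded writes, and the reachable-state set collapses to the recorded path.

## Command line

```
hhreplay record --hue green --seed 7 --out rec.csv
hhreplay replay --recording rec.csv --mode feedback --hue none
hhreplay battery --seed 7 --out runs/      # full scenario set, pass/fail
hhreplay calibrate                         # measured model parameters
hhreplay tm-demo
```

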