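# Methods

## Neuron model

Each cortical neuron is a single isopotential compartment with Na⁺, K⁺ and
leak channels:

C dV/dt = −g_L(V−E_L) − g_Na m³h(V−E_Na) − g_K n⁴(V−E_K) + I_syn + I_vc + I_ext

| parameter | value | why |
|---|---|---|
| C | 200 pF | with g_L gives τ_m = 10 ms, a typical cortical value |
| g_L | 20 nS | sets R_in = 1/g_L = 50 MΩ, the calibrated target |
| E_L | −70 mV | resting potential |
| g_Na, E_Na | 7000 nS, +50 mV | squid-ratio scaling (g_Na/g_L = 350) |
| g_K, E_K | 1800 nS, −77 mV | repolarization without depolarization block |

Gating uses Wang–Buzsáki-style rate functions rather than the classic
squid rates. The reason is quantitative: with squid kinetics the K⁺
activation n∞(−70 mV)⁴ ≈ 10⁻², contributing ≈ 24 nS of resting
conductance and pulling the input resistance to ~30 MΩ. The WB-style
curves leave both active channels essentially closed at rest
(n∞⁴ ≈ 10⁻⁵), so the measured R_in is set by the leak alone and lands at
50 MΩ without distorting g_L. Two scalar knobs are exposed:

* `phi` (default **1.0**) — the rate multiplier on the slow gates h, n.
  At this absolute conductance scale, `phi = 5` makes inactivation so fast
  that spikes fail to overshoot 0 mV and the cell enters depolarization
  block under sustained drive; `phi = 1` gives full-height spikes and
  clean repetitive firing.
* `v_shift` (default **+2 mV**) — rigid shift of all rate curves, used as
  the threshold calibration. The binding constraints are behavioural:
  one 5 nS EPSP from rest must stay subthreshold (measured peak ≈ −62 mV),
  a depressed EPSP train from a single presynaptic neuron must stay
  subthreshold, while two coincident full-strength EPSPs (≈ 10 nS) and the
  LGN train must fire the cell. A sweep showed `v_shift = 0` lets a single
  neighbour's train fire the cell (breaking red/blue selectivity) and
  `v_shift ≥ 4` blocks coincidence ignition (breaking green); +2 mV sits
  between with margin on both sides.

Integration is exponential Euler (Rush–Larsen) for the gates with rates
frozen at the step's initial voltage, and backward Euler for the voltage.
All terms of the membrane equation — channels, synapses, and the clamp —
are linear in the end-of-step voltage, so the update is a single division
and remains stable for arbitrarily stiff clamp conductances. Default
dt = 0.025 ms; spike counts at dt and dt/10 agree on random input traces
(tested), and the measured R_in changes by < 1 % between dt = 0.025 and
0.0025 ms.

Degenerate inputs: a non-finite state raises an integration error naming
the variable, neuron and time; gates cannot leave [0, 1] by construction
of the exponential update (property-tested with ±2 nA input steps).

## Synapse model

The conductance transient is a difference of exponentials
g(t) ∝ e^(−t/τ_d) − e^(−t/τ_r) with τ_d = 10 ms. The public `rise_time`
parameter is defined as the **time from the presynaptic event to the peak
of the conductance** (2 ms); the internal rise constant τ_r ≈ 0.70 ms is
solved from it by root finding, and the amplitude is normalized so one
event at full strength peaks at exactly `peak_conductance` = 5 nS. This
reading keeps both printed numbers directly measurable on a simulated
transient: an exponential fit to the tail returns τ_d, and the argmax of
the transient returns the rise time. (Interpreting the 2 ms as τ_r itself
would put the peak at 4.0 ms.)

Cortical synapses depress: an event scales the strength s ∈ (0, 1] by the
depression factor 0.5 — so after k rapid spikes the amplitude is exactly
0.5^k — and s recovers as ds/dt = (1−s)/τ_rec with τ_rec = 1 s, integrated
exactly between events. LGN afferent synapses are identical but
non-depressing. All synapses are excitatory with reversal 0 mV; events
arrive one synaptic delay (1 ms) after the presynaptic spike detection
(upward 0 mV crossing, 2 ms refractory rule), which avoids same-step
causality ambiguity and lets clamped or overwritten neurons drive their
targets exactly like free ones.

## LGN input and the hue computation

Each LGN node emits a renewal train: inter-spike interval = 2 ms
refractory + Exp(1/rate − refractory), so the effective rate equals the
nominal rate (150 s⁻¹). The stream is a pure function of (run seed,
node id) — the hue only gates which nodes are active. This seeding
contract is what makes a *congruent* replay (same hue and seed as the
recording, hence identical afferent drive) realizable.

The rate is a calibration decision: the network must ignite completely
under green in every seed, which requires the first spikes of neurons *a*
and *b* to land close enough for coincidence detection in neuron *c*.
At 100 s⁻¹ ignition failed in 3/20 seeds; at 150 s⁻¹ selectivity was
perfect over 40 seeds × 3 hues (green: all 5 fire; red: only *b*; blue:
only *a*), with network activity ceasing within 20 ms of stimulus offset
(the depression-based runaway guard). Stimulus timing defaults
(onset 100 ms, duration 300 ms, total 500 ms) are desk-scale choices
leaving pre- and post-stimulus baselines.

## Replay

A Recording stores each neuron's voltage trace bit-for-bit from an
open-loop run. Feedforward replay overwrites V every step with the
recorded value; feedback replay adds a clamp conductance g_c = 1000/R_s
[nS] pulling toward the command. Two numerical choices matter:

* **R_s = 0.05 MΩ** (clamp τ = R_s·C = 0.01 ms). The clamp's tracking lag
  scales with R_s; at 0.1 MΩ the reconstruction error of I_vc against the
  recorded LGN current peaked at 5.5 % on the faster-firing neuron, at
  0.05 MΩ the worst case over seeds is 2.8 % with ≤ 0.06 mV voltage error.
  A guard rejects R_s·C > 10·dt.
* **The command is indexed at the end of the step** (the backward-Euler
  target). With this convention a neuron whose free dynamics already
  match the command draws *exactly* zero clamp current in real
  arithmetic; in floating point the congruent-replay current is ~10⁻¹⁰ pA,
  orders of magnitude below the 1 pA tolerance used to declare a replay
  silent. Commanding the start-of-step value instead would inject
  O(nA) transients on every spike upstroke.

`classify_nothing` distinguishes clamp-off (Nothing type I) from
clamp-armed-but-silent (Nothing type II, max |I_vc| ≤ 1 pA — more than
100× below the synaptic currents here, far above float noise).
Feedforward replay is always reported as an intervention: it overwrites
the voltage every step regardless of ongoing activity. `clamp_charge`
(∫|I_vc|dt) is undefined for feedforward replay and raises.

## Scenario battery

Eight scenarios — three recordings (green/red/blue), feedforward and
feedback replay without a stimulus, feedback replay against incongruent
red and congruent green, and the clamp-off control — run off a single
base seed, sharing the green recording. Each carries a predicate encoding
the corresponding qualitative claim; the battery additionally checks that
the Nothing-I and Nothing-II green runs have identical voltages
(< 10⁻⁶ mV; measured ~10⁻¹⁴, pure float noise kept bounded by the clamp's
per-step contraction).

## Turing-machine analogue

`tm_replay` records a machine's per-step head tuples (state s, read t,
write w, move m) and replays the (w, m) sequence either verbatim
(feedforward, never consulting the transition function) or as a monitor
that lets the live machine act and overwrites only deviating proposals
(feedback). Conventions chosen where the discrete story is open:

* deviation is judged on the proposed (w, m) pair only; for deterministic
  machines also comparing s is observationally identical.
* if the live machine halts while the record continues, each remaining
  recorded pair is imposed and counted as an intervention.
* the "visited" state set is the set of states occupied when *executing*
  a step; this makes free execution on the recorded tape visit exactly
  the record's states, so the erasure statement
  reachable(replay) ⊆ reachable(free) is assertable with equality iff the
  ensemble adds no new states.

Fixture machines (a unary incrementer and a parity checker) are small
enough for brute-force oracles; they are declared in code/JSON as
fixtures, not as "the" canonical machine.

## What the synthetic data does and does not show

All inputs are synthetic by design — the artificial subject *is* the
model. The LGN trains emulate stochastic afferent drive but are renewal
processes with a hue-independent seeding contract; real afferents are
neither renewal nor replayable, so the exact-congruence results
(|I_vc| ~ 10⁻¹⁰ pA) demonstrate the clamp's null property under the
model's determinism, not an achievable laboratory number. Passing tests
show the mechanisms are implemented consistently (replay fidelity,
reconstruction, erasure), not that a biological network would behave
identically; intrinsic biological noise would turn the sharp
congruent/incongruent dichotomy into a graded one.

## Problem sizes

Tests and the acceptance script use the reference circuit (5 neurons,
2 LGN nodes) with 500 ms runs at dt = 0.025 ms (20 001 samples);
selectivity properties use 20 seeds per hue; the fine-reference
integration checks use 250 ms at dt/10. These are the package's standard
desk-scale settings.

## Known limitations

Single-compartment neurons, no temperature dependence, channel noise or
ion accumulation; voltage-only replay (gates and synaptic states are not
clamped); clamp attached to cortical neurons only; no behavioural output
stage; the discrete analogue does not attempt a universal-machine
construction or a state-usage ratio statistic beyond the two reachable-set
sizes.
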