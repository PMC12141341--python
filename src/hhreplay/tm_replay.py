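"""Discrete formalization of replay on a Turing machine.

The continuous experiments have an exact discrete analogue.  A standard
Turing machine is run on an input tape while its head operations are
recorded as a sequence of (s, t, w, m) tuples - the state it was in, the
symbol it read, the symbol it wrote and the move it made.  The recording
can then be replayed in two ways:

* **feedforward** - the recorded (w, m) sequence is imposed verbatim; the
  transition function and the tape contents are never consulted.
* **feedback** - each step the live machine proposes its own (w, m) via
  the transition function; if the proposal matches the record it is
  applied untouched, otherwise the recorded pair is imposed and an
  intervention is counted.

Both produce the identical write/move sequence, so the machine's
input/output behaviour degenerates to the recorded trajectory either
way; the feedback replay on the *recorded* tape intervenes zero times -
the discrete Nothing type II.  `reachable_state_set` exposes the erasure:
under replay, states that other tapes would have reached become
unreachable.

The deviation check compares the proposed (w, m) pair only; reads are
fixed by the tape and states follow the transition function, so for
deterministic machines also monitoring s is observationally identical.
If the live machine halts while the record continues, every remaining
recorded pair is imposed (each counting as an intervention).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MalformedSpecError

__all__ = [
    "TMSpec",
    "TMConfiguration",
    "HeadRecord",
    "TMReplayResult",
    "tm_run_and_record",
    "tm_feedforward_replay",
    "tm_feedback_replay",
    "reachable_state_set",
    "tape_from_string",
    "tape_to_string",
    "unary_incrementer",
    "parity_checker",
]

Move = str  # "L" or "R"
Tape = dict[int, str]  # sparse map position -> symbol; absent cells read blank


@dataclass(frozen=True)
class TMSpec:
    """A deterministic Turing machine.

    `transitions` maps (state, read symbol) -> (next state, write symbol,
    move); it must be total on non-halting states for every reachable
    configuration, or a MalformedSpecError is raised at run time.
    """

    states: frozenset[str]
    alphabet: frozenset[str]
    blank: str
    transitions: dict[tuple[str, str], tuple[str, str, Move]]
    initial: str
    halting: frozenset[str]

    def __post_init__(self):
        if self.blank not in self.alphabet:
            raise ValueError("blank symbol must be in the alphabet")
        if self.initial not in self.states:
            raise ValueError("initial state not in state set")
        for (s, t), (s2, w, m) in self.transitions.items():
            if m not in ("L", "R"):
                raise ValueError(f"move must be 'L' or 'R', got {m!r}")
            if s not in self.states or s2 not in self.states:
                raise ValueError(f"transition uses unknown state: {(s, s2)}")
            if t not in self.alphabet or w not in self.alphabet:
                raise ValueError(f"transition uses unknown symbol: {(t, w)}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "states": sorted(self.states),
            "alphabet": sorted(self.alphabet),
            "blank": self.blank,
            "initial": self.initial,
            "halting": sorted(self.halting),
            "rules": [
                {"state": s, "read": t, "next": s2, "write": w, "move": m}
                for (s, t), (s2, w, m) in sorted(self.transitions.items())
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TMSpec":
        doc = json.loads(Path(path).read_text())
        transitions = {
            (r["state"], r["read"]): (r["next"], r["write"], r["move"])
            for r in doc["rules"]
        }
        return cls(states=frozenset(doc["states"]),
                   alphabet=frozenset(doc["alphabet"]),
                   blank=doc["blank"],
                   transitions=transitions,
                   initial=doc["initial"],
                   halting=frozenset(doc["halting"]))


@dataclass
class TMConfiguration:
    """A machine's instantaneous description; unvisited cells read blank."""

    tape: Tape = field(default_factory=dict)
    head: int = 0
    state: str = ""
    steps: int = 0


@dataclass
class HeadRecord:
    """The recorded head trajectory: one (s, t, w, m) tuple per step."""

    steps: list[tuple[str, str, str, Move]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def visited_states(self) -> frozenset[str]:
        return frozenset(s for s, _, _, _ in self.steps)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "s", "t", "w", "m"])
            for i, (s, t, w, m) in enumerate(self.steps):
                writer.writerow([i, s, t, w, m])

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeadRecord":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(steps=[(r["s"], r["t"], r["w"], r["m"]) for r in rows])


@dataclass
class TMReplayResult:
    """Outcome of a replay run.

    `interventions` counts the steps where the replay had to overwrite the
    machine's own proposed (w, m); zero means the spontaneous trajectory
    matched the record throughout.
    """

    final_tape: Tape
    halted: bool
    interventions: int
    visited_states: frozenset[str]


def tape_from_string(s: str, offset: int = 0) -> Tape:
    """Dense string -> sparse tape with cell i holding s[i - offset]."""
    return {i + offset: ch for i, ch in enumerate(s)}


def tape_to_string(tape: Tape, blank: str = "_") -> str:
    """Sparse tape -> dense string over the written span."""
    if not tape:
        return ""
    lo, hi = min(tape), max(tape)
    return "".join(tape.get(i, blank) for i in range(lo, hi + 1))


def _delta(spec: TMSpec, state: str, symbol: str):
    try:
        return spec.transitions[(state, symbol)]
    except KeyError:
        raise MalformedSpecError(
            f"transition function undefined for (state={state!r}, "
            f"symbol={symbol!r})") from None


def tm_run_and_record(spec: TMSpec, tape: Tape,
                      max_steps: int) -> tuple[HeadRecord, Tape]:
    """Run the machine, recording one (s, t, w, m) tuple per executed step.

    Stops when a halting state is entered or after max_steps; a machine
    that starts halted yields an empty record.
    """
    if max_steps <= 0:
        raise ValueError(f"max_steps must be > 0, got {max_steps}")
    tape = dict(tape)
    state, head = spec.initial, 0
    record = HeadRecord()
    while state not in spec.halting and len(record) < max_steps:
        read = tape.get(head, spec.blank)
        state_next, write, move = _delta(spec, state, read)
        record.steps.append((state, read, write, move))
        tape[head] = write
        head += 1 if move == "R" else -1
        state = state_next
    return record, tape


def tm_feedforward_replay(record: HeadRecord, tape: Tape,
                          start: int = 0) -> TMReplayResult:
    """Impose the recorded (w, m) sequence verbatim, ignoring tape and rules.

    The write/move sequence is identical to the record regardless of the
    tape's content; visited states are the recorded ones by definition.
    """
    if len(record) == 0:
        raise ValueError("record is empty")
    tape = dict(tape)
    head = start
    for _, _, write, move in record.steps:
        tape[head] = write
        head += 1 if move == "R" else -1
    return TMReplayResult(final_tape=tape, halted=True,
                          interventions=len(record),
                          visited_states=record.visited_states)


def tm_feedback_replay(spec: TMSpec, record: HeadRecord, tape: Tape,
                       start: int = 0) -> TMReplayResult:
    """Monitor the live machine and correct deviations from the record.

    Each step the transition function proposes (w, m) for the live
    configuration; a matching proposal is applied untouched, a deviating
    (or absent, if the live machine halted early) one is replaced by the
    recorded pair and counted as an intervention.  The net write/move
    sequence always equals the record, so the final written cells match
    the feedforward replay exactly.
    """
    if len(record) == 0:
        raise ValueError("record is empty")
    tape = dict(tape)
    head = start
    state = spec.initial
    interventions = 0
    for _, _, w_rec, m_rec in record.steps:
        if state in spec.halting:
            proposal = None
            state_next = state
        else:
            read = tape.get(head, spec.blank)
            state_next, w_prop, m_prop = _delta(spec, state, read)
            proposal = (w_prop, m_prop)
        if proposal != (w_rec, m_rec):
            interventions += 1
        tape[head] = w_rec
        head += 1 if m_rec == "R" else -1
        state = state_next
    return TMReplayResult(final_tape=tape, halted=True,
                          interventions=interventions,
                          visited_states=record.visited_states)


def reachable_state_set(spec: TMSpec, tapes: list[Tape], mode: str,
                        record: HeadRecord | None = None,
                        max_steps: int = 10_000) -> frozenset[str]:
    """States visited over a finite tape ensemble.

    Free mode brute-forces the machine on each tape and unions the states
    it occupied while executing steps; replay mode is the recorded path's
    states only, independent of the ensemble — the counterfactual erasure
    made explicit as a shrunken reachable set.
    """
    if mode == "free":
        visited: set[str] = set()
        for tape in tapes:
            rec, _ = tm_run_and_record(spec, tape, max_steps)
            visited |= rec.visited_states
        return frozenset(visited)
    if mode == "feedback_replay":
        if record is None:
            raise ValueError("replay mode requires a record")
        return record.visited_states
    raise ValueError(f"unknown mode {mode!r}; expected 'free' or 'feedback_replay'")


def unary_incrementer() -> TMSpec:
    """Fixture machine: appends one '1' to a unary numeral."""
    return TMSpec(
        states=frozenset({"scan", "done"}),
        alphabet=frozenset({"1", "_"}),
        blank="_",
        transitions={
            ("scan", "1"): ("scan", "1", "R"),
            ("scan", "_"): ("done", "1", "R"),
        },
        initial="scan",
        halting=frozenset({"done"}))


def parity_checker() -> TMSpec:
    """Fixture machine: marks whether a bit string has even or odd parity."""
    return TMSpec(
        states=frozenset({"even", "odd", "accept", "reject"}),
        alphabet=frozenset({"0", "1", "E", "O", "_"}),
        blank="_",
        transitions={
            ("even", "0"): ("even", "0", "R"),
            ("even", "1"): ("odd", "1", "R"),
            ("odd", "0"): ("odd", "0", "R"),
            ("odd", "1"): ("even", "1", "R"),
            ("even", "_"): ("accept", "E", "R"),
            ("odd", "_"): ("reject", "O", "R"),
        },
        initial="even",
        halting=frozenset({"accept", "reject"}))
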