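"""Exception hierarchy for the simulator."""


class HHReplayError(Exception):
    """Base class for all package-specific errors."""


class IntegrationError(HHReplayError):
    """Numerical integration produced a non-finite state variable."""

    def __init__(self, variable: str, time_ms: float, neuron: str | int | None = None):
        self.variable = variable
        self.time_ms = time_ms
        self.neuron = neuron
        where = f" in neuron {neuron}" if neuron is not None else ""
        super().__init__(
            f"non-finite value of '{variable}'{where} at t = {time_ms:.3f} ms"
        )


class InvalidProbeError(HHReplayError):
    """Input-resistance probe was zero, depolarizing, too large, or evoked a spike."""


class InvalidTopologyError(HHReplayError):
    """Requested network wiring is impossible (e.g. fan-in >= population size)."""


class InvalidStimulusError(HHReplayError):
    """Unknown hue or malformed stimulus."""


class IncompatibleRecordingError(HHReplayError):
    """Recording's time grid does not match the requested simulation grid."""


class ConfigError(HHReplayError):
    """Configuration document violates the schema."""


class TraceFormatError(HHReplayError):
    """Trace file is malformed or inconsistent with its sidecar."""


class MalformedSpecError(HHReplayError):
    """Turing-machine transition function is undefined for a reached configuration."""


class ZeroReferenceError(HHReplayError):
    """Reference trace for a normalized error is identically zero."""


class NotApplicableError(HHReplayError):
    """Requested summary is undefined for this replay mode."""
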