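"""Shared fixtures: the reference circuit and the expensive replay runs.

Network simulations take ~1 s each, so every run that more than one test
inspects is computed once per session.
"""

from __future__ import annotations

import pytest

from hhreplay.network import HueStimulus, NetworkConfig
from hhreplay.replay import ClampParams, ReplayMode, record_reference_run, run_with_replay

SEED = 7

GREEN = HueStimulus(hue="green", onset=100.0, duration=300.0)
RED = HueStimulus(hue="red", onset=100.0, duration=300.0)
BLUE = HueStimulus(hue="blue", onset=100.0, duration=300.0)
NO_STIM = HueStimulus(hue="none", onset=100.0, duration=0.0)


@pytest.fixture(scope="session")
def config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def clamp() -> ClampParams:
    return ClampParams()


@pytest.fixture(scope="session")
def green_recording(config):
    """Reference green-stimulus run (the command voltage for all replays)."""
    return record_reference_run(config, GREEN, duration=500.0, seed=SEED)


@pytest.fixture(scope="session")
def fb_nostim(config, green_recording, clamp):
    """Feedback replay of the green recording with no visual input."""
    return run_with_replay(config, NO_STIM, green_recording,
                           ReplayMode.FEEDBACK, clamp, seed=SEED)


@pytest.fixture(scope="session")
def ff_nostim(config, green_recording):
    """Feedforward replay of the green recording with no visual input."""
    return run_with_replay(config, NO_STIM, green_recording,
                           ReplayMode.FEEDFORWARD, seed=SEED)


@pytest.fixture(scope="session")
def congruent_green(config, green_recording, clamp):
    """Feedback replay during the matching green stimulus (same seed)."""
    return run_with_replay(config, GREEN, green_recording,
                           ReplayMode.FEEDBACK, clamp, seed=SEED)


@pytest.fixture(scope="session")
def incongruent_red(config, green_recording, clamp):
    """Feedback replay of the green recording during a red stimulus."""
    return run_with_replay(config, RED, green_recording,
                           ReplayMode.FEEDBACK, clamp, seed=SEED)


@pytest.fixture(scope="session")
def clamp_off_green(config, green_recording):
    """Green stimulus with the amplifier hardware switched off."""
    return run_with_replay(config, GREEN, green_recording,
                           ReplayMode.OFF, seed=SEED)
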