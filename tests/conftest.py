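"""Shared fixtures: geometry, configs, and synthetic event/session factories."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import settings

from ebossflux import DEFAULT_GEOMETRY, RunConfig, SignalRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ebossflux.synth import EventTruth, extinction_fraction

FS = 30_517.0
T0 = datetime(2021, 7, 13, tzinfo=timezone.utc)


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(2021)


def make_insect_truth(
    *,
    start: float = 4.5,
    transit: float = 0.1,
    body_depth: float = 0.1,
    wingbeat: float = 200.0,
    wing_factor: float = 0.5,
) -> EventTruth:
    return EventTruth(
        start_time=start,
        transit_time=transit,
        body_depth=body_depth,
        wingbeat=wingbeat,
        wing_depth=wing_factor * body_depth,
        mass_dry=1.0,
        kind="insect",
    )


def make_single_event_record(
    truth: EventTruth,
    *,
    duration: float = 10.0,
    baseline: float = 2500.0,
    noise_mv: float = 0.0,
    seed: int = 0,
    sample_rate: float = FS,
) -> SignalRecord:
    """A quiet record with one event at the truth's centre time."""
    n = int(duration * sample_rate)
    t = np.arange(n) / sample_rate
    sig = baseline * (1.0 - extinction_fraction(t, truth, center=truth.center_time))
    if noise_mv > 0:
        sig = sig + np.random.default_rng(seed).normal(0.0, noise_mv, n)
    return SignalRecord(samples=sig, sample_rate=sample_rate, start_time=T0)
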