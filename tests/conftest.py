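from __future__ import annotations

from datetime import datetime, timedelta, timezone
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


class FrozenClock:
    """Deterministic clock: fixed instant, optionally ticking per call."""

    def __init__(self, start: datetime | None = None, tick: float = 0.0):
        self.now = start or datetime(2020, 5, 17, 12, 0, 0,
                                     tzinfo=timezone.utc)
        self.tick = tick

    def __call__(self) -> datetime:
        current = self.now
        self.now = self.now + timedelta(seconds=self.tick)
        return current

    def advance(self, seconds: float) -> None:
        self.now = self.now + timedelta(seconds=seconds)


@pytest.fixture
def frozen_clock() -> FrozenClock:
    return FrozenClock()


@pytest.fixture
def local_machines(tmp_path: Path):
    """Two local stub machines with 2 and 5 simulator slots (pool of 7)."""
    from simbatch.fixtures import make_local_machineset

    return make_local_machineset(tmp_path / "machines", counts=(2, 5))


def sine_config(tmp_path: Path, machines, **overrides):
    from simbatch.engine import EngineConfig

    defaults = dict(
        session_name="test",
        sim_type="sine01",
        root=str(tmp_path / "sessions"),
        machines=machines,
        poll_interval=0.02,
        wall_time=60.0,
    )
    defaults.update(overrides)
    return EngineConfig(**defaults)


@pytest.fixture
def run_sine_session(tmp_path, local_machines):
    """Run a 3-simulation sine session on the 7-slot local pool."""
    from simbatch.core import parse_simspec
    from simbatch.engine import run_from_simset

    def _run(simspec_text: str | None = None, **overrides):
        text = simspec_text or (
            "s1\t1\t0.1\n"
            "s2\t2\t0.1\n"
            "s3\t0.5\t0.1\n"
        )
        simset = parse_simspec(text, "fixture")
        cfg = sine_config(tmp_path, local_machines, **overrides)
        return run_from_simset(cfg, simset)

    return _run
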