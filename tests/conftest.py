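import numpy as np
import pytest

from sausi.io_sessions import (
    ANIMAL_NAMES,
    NODE_NAMES,
    EthogramEvent,
    EventLog,
    KeypointTrajectory,
    SessionRecord,
)
from sausi.synthetic import ConditionParams, GeneratorConfig, simulate_session
from sausi.vocabulary import BEHAVIOR_REGISTRY, POINT, STATE, allowed_actor


@pytest.fixture(scope="session")
def tiny_cfg() -> GeneratorConfig:
    """Short sessions (30 s baseline + 120 s test) for fast unit tests."""
    return GeneratorConfig(baseline_s=30.0, test_s=120.0)


@pytest.fixture(scope="session")
def gh_session(tiny_cfg):
    return simulate_session(tiny_cfg, "GH", seed=11)


@pytest.fixture(scope="session")
def si_session(tiny_cfg):
    return simulate_session(tiny_cfg, "SI", seed=12)


def make_trajectory(
    n_frames: int = 10, fps: float = 30.0, seed: int = 0, all_valid: bool = True
) -> KeypointTrajectory:
    """A random but structurally valid trajectory."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(1.0, 29.0, size=(n_frames, 2, 8, 2))
    valid = np.ones((n_frames, 2, 8), dtype=bool)
    if not all_valid:
        valid[rng.random(valid.shape) < 0.2] = False
        coords[~valid] = np.nan
    return KeypointTrajectory(coords, valid, fps)


def random_event_log(rng: np.random.Generator, t_max: float = 780.0) -> EventLog:
    """Random log covering the whole behavior vocabulary."""
    events = []
    for behavior, (etype, actor) in BEHAVIOR_REGISTRY.items():
        for _ in range(rng.poisson(3)):
            onset = float(rng.uniform(0, t_max))
            if etype == STATE:
                events.append(
                    EthogramEvent(
                        behavior, actor, STATE, onset,
                        onset + float(rng.exponential(5.0)),
                    )
                )
            else:
                events.append(EthogramEvent(behavior, actor, POINT, onset))
    return EventLog(events)
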