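import pytest

from trophamix import (
    ColonySchedule,
    InteractionEvent,
    SyntheticColonyConfig,
    generate_colony,
    track_provenance,
)


@pytest.fixture(scope="session")
def default_colony():
    """Default synthetic colony: 70 ants, 5 foragers, delta=0.26, ~700 events."""
    return generate_colony(SyntheticColonyConfig(seed=42))


@pytest.fixture(scope="session")
def default_trace(default_colony):
    schedule, _, _ = default_colony
    return track_provenance(schedule)


@pytest.fixture(scope="session")
def heterogeneous_colony():
    """Synthetic colony with lognormal crop capacities."""
    cfg = SyntheticColonyConfig(seed=11, capacity_lognormal_sigma=0.4)
    return generate_colony(cfg)


@pytest.fixture()
def tiny_schedule():
    """Hand-built schedule: one forager loading twice, two workers."""
    events = [
        InteractionEvent("T", 0.0, "SOURCE", "F1", 8.0),
        InteractionEvent("T", 1.0, "F1", "W1", 2.0),
        InteractionEvent("T", 2.0, "F1", "W1", 0.9),
        InteractionEvent("T", 3.0, "W1", "W2", 1.0),
    ]
    return ColonySchedule(colony_id="T", events=events, foragers=["F1"])
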