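"""Synthetic colonies with known ground-truth provenance.

The generator emulates the statistical structure of a famine-relief
experiment: all crops start empty; a small forager subset shuttles
between the food source and the nest, reloading whenever its crop runs
low; forager→non-forager and non-forager↔non-forager events occur in the
empirical ~1:1.9 ratio; every transferred volume is ṽ·v_max with ṽ drawn
from the truncated-exponential transfer rule with scale δ; crops have
finite capacities (constant, or lognormal for heterogeneity).

The generator keeps its own event-by-event provenance bookkeeping with
plain per-ant dictionaries — a deliberately separate code path from the
tracking module — so tracking can be validated against it as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import SOURCE, ColonySchedule, InteractionEvent

#: Empirical forager→non-forager share of ant-to-ant events (713 of 2070).
DEFAULT_FORAGER_EVENT_FRACTION = 713 / 2070


@dataclass
class SyntheticColonyConfig:
    """Everything needed to generate one colony reproducibly.

    Defaults mirror the experimental colonies: 70 ants of which 5 forage,
    δ = 0.26, ~700 trophallactic events, unit capacities.  A forager
    returns to the source whenever its load drops below
    ``reload_threshold`` of its capacity, loading ``trip_volume`` (or
    filling up when None).
    """

    n_ants: int = 70
    n_foragers: int = 5
    capacity: float = 1.0
    capacity_lognormal_sigma: float | None = None
    delta: float = 0.26
    trip_volume: float | None = None
    reload_threshold: float = 0.2
    forager_event_fraction: float = DEFAULT_FORAGER_EVENT_FRACTION
    total_events: int = 700
    seed: int = 0
    colony_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 1 <= self.n_foragers < self.n_ants:
            raise ValueError("need 1 <= n_foragers < n_ants")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0.0 <= self.forager_event_fraction <= 1.0:
            raise ValueError("forager_event_fraction must lie in [0, 1]")
        if self.total_events < 1:
            raise ValueError("total_events must be >= 1")
        if self.trip_volume is not None and self.trip_volume <= 0:
            raise ValueError("trip_volume must be positive")


@dataclass
class GroundTruth:
    """The generator's own record of the colony's provenance history.

    ``snapshots[k]`` maps ant -> {food type -> amount} *after* event ``k-1``
    (``snapshots[0]`` is the initial all-empty state), aligned with the
    emitted schedule.  ``v_tilde`` lists the drawn transfer fractions of
    the ant-to-ant events, in order.
    """

    config: SyntheticColonyConfig
    ants: list[str]
    foragers: list[str]
    snapshots: list[dict[str, dict[str, float]]] = field(repr=False)
    v_tilde: list[float] = field(repr=False)
    event_kinds: list[str] = field(repr=False)  # "source" | "fn" | "nn"

    def amounts_array(self, ants, types) -> np.ndarray:
        """Snapshots as an array aligned with a tracking trace's layout."""
        ants, types = list(ants), list(types)
        out = np.zeros((len(self.snapshots), len(ants), len(types)))
        for k, snap in enumerate(self.snapshots):
            for i, a in enumerate(ants):
                crop = snap[a]
                for j, t in enumerate(types):
                    out[k, i, j] = crop[t]
        return out

    def final_composition(self, ant: str) -> dict[str, float]:
        crop = self.snapshots[-1][ant]
        tot = sum(crop.values())
        if tot <= 0:
            raise ValueError(f"{ant!r} holds no food")
        return {t: a / tot for t, a in crop.items()}


def _draw_v_tilde(delta: float, rng: np.random.Generator) -> float:
    # inverse CDF of the truncated exponential on [0, 1]
    u = rng.random()
    return -delta * math.log1p(u * math.expm1(-1.0 / delta))


def generate_colony(
    config: SyntheticColonyConfig,
) -> tuple[ColonySchedule, GroundTruth, dict[str, float]]:
    """Generate a schedule, its ground-truth provenance, and true capacities.

    The schedule interleaves source-loading events (whenever a forager's
    crop drops below its reload threshold) with ``total_events``
    ant-to-ant events.  Early non-forager events fall back to forager
    events while no non-forager holds food yet, mirroring the onset of a
    real famine-relief experiment.
    """
    rng = np.random.default_rng(config.seed)
    nf = config.n_foragers
    foragers = [f"F{i + 1}" for i in range(nf)]
    workers = [f"W{i + 1:03d}" for i in range(config.n_ants - nf)]
    ants = foragers + workers

    if config.capacity_lognormal_sigma:
        sigma = config.capacity_lognormal_sigma
        mu = math.log(config.capacity) - 0.5 * sigma**2
        capacities = {a: float(np.exp(rng.normal(mu, sigma))) for a in ants}
    else:
        capacities = {a: config.capacity for a in ants}

    crops: dict[str, dict[str, float]] = {
        a: {t: 0.0 for t in foragers} for a in ants
    }
    loads = {a: 0.0 for a in ants}

    events: list[InteractionEvent] = []
    snapshots = [ {a: dict(c) for a, c in crops.items()} ]
    v_tildes: list[float] = []
    kinds: list[str] = []
    t = 0.0

    def snapshot() -> None:
        snapshots.append({a: dict(c) for a, c in crops.items()})

    def reload_foragers() -> None:
        nonlocal t
        for f in foragers:
            cap = capacities[f]
            if loads[f] < config.reload_threshold * cap:
                vol = config.trip_volume if config.trip_volume is not None else cap - loads[f]
                vol = min(vol, cap - loads[f])
                if vol <= 0:
                    continue
                t += 1.0
                events.append(
                    InteractionEvent(config.colony_id, t, SOURCE, f, vol)
                )
                crops[f][f] += vol
                loads[f] += vol
                kinds.append("source")
                snapshot()

    def transfer(donor: str, recipient: str, v: float) -> None:
        crop_d = crops[donor]
        v_donor = sum(crop_d.values())
        frac = v / v_donor
        crop_r = crops[recipient]
        moved_total = 0.0
        for typ in foragers:
            moved = frac * crop_d[typ]
            crop_r[typ] += moved
            crop_d[typ] -= moved
            moved_total += moved
        loads[donor] -= moved_total
        loads[recipient] += moved_total

    n_emitted = 0
    while n_emitted < config.total_events:
        reload_foragers()
        want_fn = rng.random() < config.forager_event_fraction
        if not want_fn:
            eligible_donors = [w for w in workers if loads[w] > 0]
            if not eligible_donors:
                want_fn = True  # nobody downstream holds food yet
        if want_fn:
            donor = foragers[int(rng.integers(nf))]
            recips = [w for w in workers if capacities[w] - loads[w] > 1e-12]
            kind = "fn"
        else:
            donor = eligible_donors[int(rng.integers(len(eligible_donors)))]
            recips = [
                w for w in workers
                if w != donor and capacities[w] - loads[w] > 1e-12
            ]
            kind = "nn"
        if not recips:
            raise ValueError(
                "colony is saturated: no recipient has free space; "
                "reduce total_events or raise capacities"
            )
        recipient = recips[int(rng.integers(len(recips)))]
        v_max = min(loads[donor], capacities[recipient] - loads[recipient])
        if v_max <= 0:
            continue  # donor momentarily empty; redraw
        vt = _draw_v_tilde(config.delta, rng)
        v = vt * v_max
        t += 1.0
        events.append(InteractionEvent(config.colony_id, t, donor, recipient, v))
        transfer(donor, recipient, v)
        kinds.append(kind)
        v_tildes.append(vt)
        snapshot()
        n_emitted += 1

    schedule = ColonySchedule(
        colony_id=config.colony_id,
        events=events,
        foragers=list(foragers),
        capacities=dict(capacities),
    )
    truth = GroundTruth(
        config=config,
        ants=ants,
        foragers=foragers,
        snapshots=snapshots,
        v_tilde=v_tildes,
        event_kinds=kinds,
    )
    return schedule, truth, capacities
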