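"""The δ̃ trade-off model: food accumulation versus food mixing.

A deliberately minimal model isolating the role of the transferred
fraction.  All ants share one crop capacity; foragers start holding all
the food they will ever deliver (M/n_foragers each, of their own pure
type) so the colony-wide total M is conserved; interactions occur at
random with the empirical ratio of forager→non-forager to
non-forager↔non-forager events; every transfer is the deterministic
fraction δ̃ of the transfer potential, v = δ̃·v_max.

Large δ̃ accumulates food quickly (P_colony, the satiation level, rises
fast) but near-full crops can no longer change composition, so mixing
among non-foragers (H_mix) suffers.  Their product, the overall mixing
entropy H_mix^overall = P_colony·H_mix (exact here because forager crops
stay pure), exhibits a broad interior maximum in δ̃.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Empirical forager→non-forager share of ant-to-ant events (713 of 2070).
EMPIRICAL_FORAGER_EVENT_FRACTION = 713 / 2070


@dataclass
class TradeoffConfig:
    """Parameters of the δ̃ model.

    ``total_food`` (M) defaults to half the aggregate non-forager capacity
    so the colony can comfortably absorb all of it; foragers hold
    M/n_foragers at t = 0 and never receive.  The interaction budget is
    ``mean_interactions_per_ant * n_ants / 2`` events.
    """

    n_ants: int = 70
    n_foragers: int = 5
    capacity: float = 1.0
    total_food: float | None = None
    delta_tilde: float = 0.26
    mean_interactions_per_ant: float = 20.0
    forager_event_fraction: float = EMPIRICAL_FORAGER_EVENT_FRACTION
    n_reps: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_food is None:
            self.total_food = 0.5 * (self.n_ants - self.n_foragers) * self.capacity
        self.validate()

    def validate(self) -> None:
        if not 1 <= self.n_foragers < self.n_ants:
            raise ValueError("need 1 <= n_foragers < n_ants")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if not 0.0 < self.delta_tilde <= 1.0:
            raise ValueError("delta_tilde must lie in (0, 1]")
        if not 0.0 <= self.forager_event_fraction <= 1.0:
            raise ValueError("forager_event_fraction must lie in [0, 1]")
        max_absorbable = (self.n_ants - self.n_foragers) * self.capacity
        if self.total_food > max_absorbable:
            raise ValueError(
                f"total food {self.total_food} exceeds colony capacity "
                f"{max_absorbable}: cannot be placed"
            )

    @property
    def n_events(self) -> int:
        return int(round(self.mean_interactions_per_ant * self.n_ants / 2))


@dataclass
class TradeoffTrajectory:
    """Per-interaction trajectory of the model's summary quantities."""

    config: TradeoffConfig
    p_colony: np.ndarray
    h_mix: np.ndarray
    h_overall: np.ndarray
    std_crop_entropy: np.ndarray  # across non-forager crops holding food

    @property
    def final(self) -> dict[str, float]:
        return {
            "p_colony": float(self.p_colony[-1]),
            "h_mix": float(self.h_mix[-1]),
            "h_overall": float(self.h_overall[-1]),
            "std_crop_entropy": float(self.std_crop_entropy[-1]),
        }


def _row_entropies(amounts: np.ndarray) -> np.ndarray:
    tot = amounts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, amounts / np.where(tot > 0, tot, 1.0), 0.0)
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def simulate_tradeoff(
    config: TradeoffConfig, rng: np.random.Generator | None = None
) -> TradeoffTrajectory:
    """Run one realization of the δ̃ model.

    Foragers (indices 0..n_foragers-1) act as reservoirs: their initial
    holding M/n_foragers may exceed the common capacity, which binds only
    recipients through v_max = min(donor load, recipient free space).
    Direction among non-forager pairs is uniform at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, nf = config.n_ants, config.n_foragers
    cap = config.capacity
    m_total = config.total_food
    amounts = np.zeros((n, nf))
    for f in range(nf):
        amounts[f, f] = m_total / nf
    p_colony = np.empty(config.n_events)
    h_mix = np.empty(config.n_events)
    h_overall = np.empty(config.n_events)
    std_h = np.empty(config.n_events)
    workers = np.arange(nf, n)
    for k in range(config.n_events):
        if rng.random() < config.forager_event_fraction:
            di = int(rng.integers(0, nf))
            ri = int(rng.integers(nf, n))
        else:
            ri_, di_ = rng.choice(workers, size=2, replace=False)
            di, ri = int(di_), int(ri_)
        load_d = amounts[di].sum()
        load_r = amounts[ri].sum()
        v_max = min(load_d, max(cap - load_r, 0.0))
        v = config.delta_tilde * v_max
        if v > 0:
            frac = v / load_d
            moved = frac * amounts[di]
            amounts[ri] += moved
            amounts[di] -= moved
        loads = amounts.sum(axis=1)
        z = loads[nf:].sum()
        p_colony[k] = z / m_total
        h_rows = _row_entropies(amounts)
        h_mix[k] = ((loads[nf:] / z) * h_rows[nf:]).sum() if z > 0 else 0.0
        h_overall[k] = ((loads / m_total) * h_rows).sum()
        # spread of mixing across individuals: loaded non-forager crops.
        # Empty crops have no composition; forager crops are pure by
        # construction, and counting their zeros would conflate satiation
        # with the uniformity of mixing.
        loaded = loads[nf:] > 1e-12
        std_h[k] = h_rows[nf:][loaded].std() if loaded.any() else 0.0
    return TradeoffTrajectory(
        config=config,
        p_colony=p_colony,
        h_mix=h_mix,
        h_overall=h_overall,
        std_crop_entropy=std_h,
    )


@dataclass
class SweepResult:
    """Endpoint summaries of the δ̃ sweep, one row per grid point."""

    grid: np.ndarray
    table: pd.DataFrame = field(repr=False)

    def column(self, metric: str, stat: str = "mean") -> np.ndarray:
        return self.table[f"{metric}_{stat}"].to_numpy()


def sweep_delta(
    config: TradeoffConfig, delta_grid, n_reps: int | None = None
) -> SweepResult:
    """Sweep δ̃ over a grid, summarizing final-interaction quantities.

    Each grid point runs ``n_reps`` replicates; replicate r uses seed
    ``config.seed + r`` at every grid point (common random numbers), so
    curves across δ̃ are directly comparable.
    """
    grid = np.asarray(list(delta_grid), dtype=float)
    if ((grid <= 0) | (grid > 1)).any():
        raise ValueError("delta grid must lie in (0, 1]")
    if n_reps is None:
        n_reps = config.n_reps
    rows = []
    for dt in grid:
        cfg = TradeoffConfig(
            n_ants=config.n_ants,
            n_foragers=config.n_foragers,
            capacity=config.capacity,
            total_food=config.total_food,
            delta_tilde=float(dt),
            mean_interactions_per_ant=config.mean_interactions_per_ant,
            forager_event_fraction=config.forager_event_fraction,
            n_reps=n_reps,
            seed=config.seed,
        )
        finals = {"p_colony": [], "h_mix": [], "h_overall": [], "std_crop_entropy": []}
        for r in range(n_reps):
            traj = simulate_tradeoff(cfg, np.random.default_rng(config.seed + r))
            for key, val in traj.final.items():
                finals[key].append(val)
        row = {"delta_tilde": float(dt)}
        for key, vals in finals.items():
            arr = np.array(vals)
            row[f"{key}_mean"] = arr.mean()
            row[f"{key}_std"] = arr.std()
        rows.append(row)
    return SweepResult(grid=grid, table=pd.DataFrame(rows))
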