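"""Hybrid simulations: empirical schedule, substituted interaction rules.

Each simulation keeps part of the measured record (the time-ordered pair
schedule, including forager source-loading events) and replaces the rest:

* ``empirical_replay``     — recorded directions and volumes (sanity rule).
* ``stochastic_empirical`` — direction uniform at random on the recorded
  pair; volume v = ṽ·v_max with ṽ drawn from the truncated-exponential
  transfer rule.
* ``maximal_mixing``       — both ants pool their crops and split equally,
  leaving with identical loads and compositions; deliberately ignores
  crop capacities.
* ``max_transfer``         — the recorded donor transfers the full v_max
  (the δ ≫ 1 limit).
* ``no_secondary``         — forager-donor events follow the stochastic
  rule; non-forager-donor events transfer nothing (the δ = 0 limit for
  secondary interactions).

Comparing the resulting mixing-entropy trajectories isolates whether the
interaction network or the transfer rule limits food blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import EntropyTrace, entropy_trace
from .io import SOURCE, ColonySchedule, InteractionEvent
from .tracking import CropState, ProvenanceTrace, _apply_inplace
from .transfer import sample_truncated_exp

RULE_KINDS = (
    "empirical_replay",
    "stochastic_empirical",
    "maximal_mixing",
    "max_transfer",
    "no_secondary",
)

_CAP_TOL = 1e-9


@dataclass(frozen=True)
class RuleSpec:
    """Which interaction rule a hybrid simulation substitutes.

    ``delta`` parameterizes the stochastic truncated-exponential rule;
    ``respects_capacity`` is informational: every rule except
    ``maximal_mixing`` stays within crop capacities by construction.
    """

    kind: str
    delta: float = 0.26
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}; one of {RULE_KINDS}")

    @property
    def respects_capacity(self) -> bool:
        return self.kind != "maximal_mixing"

    @property
    def stochastic(self) -> bool:
        return self.kind in ("stochastic_empirical", "no_secondary")


def simulate_schedule(
    schedule: ColonySchedule,
    rule: RuleSpec,
    capacities: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ProvenanceTrace:
    """Replay a schedule under a substituted interaction rule.

    Source events are always applied as recorded.  ``capacities`` are
    required for the rules that compute v_max (stochastic_empirical,
    max_transfer, no_secondary).  Under a capacity-respecting rule any
    capacity violation is an internal error.
    """
    if not schedule.foragers:
        raise ValueError("schedule has no foragers")
    needs_caps = rule.kind in ("stochastic_empirical", "max_transfer", "no_secondary")
    if needs_caps and capacities is None:
        raise ValueError(f"rule {rule.kind!r} requires capacities")
    if rng is None:
        rng = np.random.default_rng(rule.seed)
    ants = tuple(schedule.ants)
    types = tuple(schedule.foragers)
    foragers = set(schedule.foragers)
    state = CropState.empty(ants, types)
    amounts = np.empty((len(schedule.events) + 1, len(ants), len(types)))
    amounts[0] = state.amounts
    idx = state._index
    for k, ev in enumerate(schedule.events):
        if ev.is_source_event:
            _apply_inplace(state, ev, event_index=k)
            amounts[k + 1] = state.amounts
            continue
        donor, recipient = ev.donor, ev.recipient
        if rule.kind == "empirical_replay":
            _apply_inplace(state, ev, event_index=k)
            amounts[k + 1] = state.amounts
            continue
        if rule.kind == "maximal_mixing":
            di, ri = idx[donor], idx[recipient]
            pooled = 0.5 * (state.amounts[di] + state.amounts[ri])
            state.amounts[di] = pooled
            state.amounts[ri] = pooled.copy()
            amounts[k + 1] = state.amounts
            continue
        if rule.kind == "stochastic_empirical" and rng.random() < 0.5:
            donor, recipient = recipient, donor
        if rule.kind == "no_secondary" and donor not in foragers:
            v = 0.0
        else:
            di, ri = idx[donor], idx[recipient]
            load_d = state.amounts[di].sum()
            load_r = state.amounts[ri].sum()
            free_r = max(capacities[recipient] - load_r, 0.0)
            v_max = min(load_d, free_r)
            if v_max <= 0:
                v = 0.0
            elif rule.kind == "max_transfer":
                v = v_max
            else:
                v = float(sample_truncated_exp(rule.delta, None, rng)) * v_max
        if v > 0:
            _apply_inplace(
                state,
                InteractionEvent(ev.colony_id, ev.time, donor, recipient, v),
                event_index=k,
            )
            if rule.respects_capacity:
                load = state.amounts[idx[recipient]].sum()
                cap = capacities[recipient]
                assert load <= cap + _CAP_TOL * max(cap, 1.0), (
                    f"internal error: capacity violated for {recipient!r} at {k}"
                )
        amounts[k + 1] = state.amounts
    return ProvenanceTrace(schedule=schedule, ants=ants, types=types, amounts=amounts)


def shuffle_identities(schedule: ColonySchedule, seed: int) -> ColonySchedule:
    """Shuffle ant identities in the schedule, preserving per-ant activity.

    All ant-label slots of ant-to-ant events are permuted uniformly at
    random, so each ant keeps its number of interaction slots while the
    who-meets-whom structure is randomized.  Source events are untouched.
    Self-pairings produced by the permutation are resolved by swapping with
    randomly chosen other slots.
    """
    rng = np.random.default_rng(seed)
    troph = [(i, e) for i, e in enumerate(schedule.events) if not e.is_source_event]
    slots: list[str] = []
    for _, e in troph:
        slots.extend((e.donor, e.recipient))
    slots = [slots[j] for j in rng.permutation(len(slots))]
    for _ in range(10_000):
        bad = [m for m in range(len(troph)) if slots[2 * m] == slots[2 * m + 1]]
        if not bad:
            break
        for m in bad:
            j = int(rng.integers(len(slots)))
            slots[2 * m + 1], slots[j] = slots[j], slots[2 * m + 1]
    else:  # pragma: no cover - pathological schedules only
        raise RuntimeError("could not resolve self-pairings")
    events = list(schedule.events)
    for m, (i, e) in enumerate(troph):
        events[i] = InteractionEvent(
            e.colony_id, e.time, slots[2 * m], slots[2 * m + 1], e.volume, e.ambiguous
        )
    return ColonySchedule(
        colony_id=schedule.colony_id,
        events=events,
        foragers=list(schedule.foragers),
        capacities=schedule.capacities,
    )


@dataclass
class EnsembleResult:
    """Mean and standard deviation of entropy trajectories over replicates."""

    rule: RuleSpec
    n_reps: int
    base_seed: int
    h_mix_mean: np.ndarray
    h_mix_std: np.ndarray
    h_types_mean: np.ndarray
    h_types_std: np.ndarray
    traces: list[EntropyTrace] = field(default_factory=list, repr=False)

    @property
    def final_h_mix(self) -> float:
        return float(self.h_mix_mean[-1])

    @property
    def final_h_types(self) -> float:
        return float(self.h_types_mean[-1])


def run_ensemble(
    schedule: ColonySchedule,
    rule: RuleSpec,
    capacities: dict[str, float] | None = None,
    n_reps: int = 30,
    base_seed: int = 0,
    keep_traces: bool = False,
) -> EnsembleResult:
    """Run ``n_reps`` replicate simulations; replicate r seeds with base_seed+r."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    h_mix = []
    h_types = []
    kept = []
    for r in range(n_reps):
        rng = np.random.default_rng(base_seed + r)
        trace = simulate_schedule(schedule, rule, capacities, rng)
        et = entropy_trace(trace)
        h_mix.append(et.h_mix)
        h_types.append(et.h_types)
        if keep_traces:
            kept.append(et)
    h_mix = np.array(h_mix)
    h_types = np.array(h_types)
    return EnsembleResult(
        rule=rule,
        n_reps=n_reps,
        base_seed=base_seed,
        h_mix_mean=h_mix.mean(axis=0),
        h_mix_std=h_mix.std(axis=0),
        h_types_mean=h_types.mean(axis=0),
        h_types_std=h_types.std(axis=0),
        traces=kept,
    )
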