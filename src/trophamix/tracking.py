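"""Food-type provenance tracking through an interaction schedule.

Food is labelled by the identity of the forager that first collected it at
the source ("food types").  Assuming food mixes instantaneously inside a
crop, each transfer moves a fraction ``v / V_donor`` of the donor's crop,
type by type:

    n'_recv(f) = n_recv(f) + (v / V_donor) * n_donor(f)

with the donor losing the same amounts.  Source-feeding events add pure
own-type food to the forager's crop.  The absolute "droplets per unit
volume" scale is arbitrary and cancels in every reported probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SOURCE, ColonySchedule, InteractionEvent

#: Relative tolerance (vs. total food M) below which float negatives clamp to 0.
CLAMP_RTOL = 1e-9


class InfeasibleTransferError(ValueError):
    """An event asks a donor for more food than its crop holds."""


@dataclass
class CropState:
    """Per-ant crop contents partitioned by food type.

    ``amounts[i, j]`` is the amount of food of type ``types[j]`` (i.e.
    collected by that forager) in the crop of ``ants[i]``, in crop units.
    """

    ants: tuple[str, ...]
    types: tuple[str, ...]
    amounts: np.ndarray  # (n_ants, n_types), non-negative

    def __post_init__(self) -> None:
        self.amounts = np.asarray(self.amounts, dtype=float)
        self._index = {a: i for i, a in enumerate(self.ants)}
        self._tindex = {t: j for j, t in enumerate(self.types)}

    @classmethod
    def empty(cls, ants, types) -> "CropState":
        ants, types = tuple(ants), tuple(types)
        return cls(ants, types, np.zeros((len(ants), len(types))))

    def load(self, ant: str) -> float:
        """Total crop content of one ant."""
        return float(self.amounts[self._index[ant]].sum())

    def crop(self, ant: str) -> np.ndarray:
        return self.amounts[self._index[ant]]

    def total(self) -> float:
        """Total food over all ants (M)."""
        return float(self.amounts.sum())

    def copy(self) -> "CropState":
        return CropState(self.ants, self.types, self.amounts.copy())


def apply_interaction(
    state: CropState, event: InteractionEvent, event_index: int | None = None
) -> CropState:
    """Apply one event to a crop state, returning the new state.

    Source events add volume ``v`` of the recipient's own pure type (the
    recipient must be a forager).  Ant-to-ant events move the fraction
    ``v / V_donor`` of the donor's composition.  Total food is conserved
    for ant-to-ant events and grows by ``v`` at source events.
    """
    out = state.copy()
    _apply_inplace(out, event, event_index)
    return out


def _apply_inplace(
    state: CropState, event: InteractionEvent, event_index: int | None = None
) -> None:
    where = "" if event_index is None else f" (event {event_index})"
    amounts = state.amounts
    ri = state._index[event.recipient]
    v = event.volume
    if event.donor == SOURCE:
        tj = state._tindex.get(event.recipient)
        if tj is None:
            raise InfeasibleTransferError(
                f"SOURCE event feeds non-forager {event.recipient!r}{where}"
            )
        amounts[ri, tj] += v
        return
    di = state._index[event.donor]
    if v == 0.0:
        return
    v_donor = amounts[di].sum()
    tol = CLAMP_RTOL * max(amounts.sum(), 1.0)
    if v_donor <= 0.0 or v > v_donor + tol:
        raise InfeasibleTransferError(
            f"donor {event.donor!r} holds {v_donor:.6g} but gives {v:.6g}{where}"
        )
    frac = min(v / v_donor, 1.0)
    moved = frac * amounts[di]
    amounts[ri] += moved
    amounts[di] -= moved
    # clamp float dust; anything larger is a genuine accounting error
    neg = amounts[di] < 0
    if neg.any():
        worst = amounts[di][neg].min()
        if -worst > tol:
            raise InfeasibleTransferError(
                f"negative crop amount {worst:.3g} for {event.donor!r}{where}"
            )
        amounts[di][neg] = 0.0


@dataclass
class ProvenanceTrace:
    """Time series of crop compositions along an interaction schedule.

    ``amounts[k]`` is the crop matrix *before* event ``k``;
    ``amounts[k + 1]`` is the state after it.  All distributions follow the
    convention that ``Z`` (and hence ``P_a``, ``P_{f,a}``, ``P_f``) is
    taken over non-forager ants only, while ``M`` and ``P_colony = Z / M``
    involve the total over all ants.
    """

    schedule: ColonySchedule
    ants: tuple[str, ...]
    types: tuple[str, ...]
    amounts: np.ndarray  # (n_events + 1, n_ants, n_types)

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.ants)}
        forg = set(self.schedule.foragers)
        self.nonforager_mask = np.array([a not in forg for a in self.ants])
        self.forager_mask = ~self.nonforager_mask

    @property
    def n_events(self) -> int:
        return self.amounts.shape[0] - 1

    # -- state access ------------------------------------------------------
    def state_after(self, index: int) -> np.ndarray:
        """Crop matrix after event ``index`` (0-based)."""
        return self.amounts[index + 1]

    def state_before(self, index: int) -> np.ndarray:
        return self.amounts[index]

    def loads(self) -> np.ndarray:
        """Per-step total crop load, shape (n_events + 1, n_ants)."""
        return self.amounts.sum(axis=2)

    # -- distributions at one index ---------------------------------------
    def Z(self, index: int) -> float:
        """Total food over non-foragers after event ``index``."""
        return float(self.state_after(index)[self.nonforager_mask].sum())

    def M(self, index: int) -> float:
        """Total food over all ants after event ``index``."""
        return float(self.state_after(index).sum())

    def P_colony(self, index: int) -> float:
        """Fraction of all food residing in non-forager crops (satiation)."""
        m = self.M(index)
        return self.Z(index) / m if m > 0 else 0.0

    def P_fa(self, index: int) -> np.ndarray:
        """Joint P_{f,a} over non-foragers, shape (n_nonforagers, n_types)."""
        z = self.Z(index)
        if z <= 0:
            raise ValueError(f"Z=0 at index {index}: P_fa undefined")
        return self.state_after(index)[self.nonforager_mask] / z

    def P_a(self, index: int) -> np.ndarray:
        return self.P_fa(index).sum(axis=1)

    def P_f(self, index: int) -> np.ndarray:
        return self.P_fa(index).sum(axis=0)

    def P_a_tilde(self, index: int) -> np.ndarray:
        """Per-ant share of the colony-wide total M, over all ants."""
        m = self.M(index)
        if m <= 0:
            raise ValueError(f"M=0 at index {index}")
        return self.state_after(index).sum(axis=1) / m

    @property
    def nonforager_labels(self) -> list[str]:
        return [a for a, nf in zip(self.ants, self.nonforager_mask) if nf]

    def crop_composition(self, ant: str, index: int) -> np.ndarray:
        """Food-type mixture P(f | A = ant) in one crop after event ``index``."""
        row = self.state_after(index)[self._index[ant]]
        tot = row.sum()
        if tot <= 0:
            raise ValueError(f"composition undefined: {ant!r} holds no food")
        return row / tot

    def final_compositions(self) -> dict[str, np.ndarray]:
        """P(f|A=a) at the last event for every ant holding food."""
        out = {}
        for ant in self.ants:
            row = self.amounts[-1][self._index[ant]]
            if row.sum() > 0:
                out[ant] = row / row.sum()
        return out

    def to_frame(self) -> "pd.DataFrame":
        """Long-format export: event_index, ant, food_type, amount."""
        import pandas as pd

        k, i, j = np.nonzero(self.amounts)
        return pd.DataFrame(
            {
                "event_index": k - 1,  # -1 denotes the initial state
                "ant": [self.ants[x] for x in i],
                "food_type": [self.types[x] for x in j],
                "amount": self.amounts[k, i, j],
            }
        )


def track_provenance(
    schedule: ColonySchedule,
    initial: CropState | None = None,
    zero_ambiguous: bool = False,
) -> ProvenanceTrace:
    """Propagate food-type provenance through a full schedule.

    Starts from empty crops (famine relief) unless ``initial`` is given.
    ``zero_ambiguous=True`` treats direction-ambiguous events as
    zero-volume contacts instead of applying their recorded volume.
    """
    if not schedule.foragers:
        raise ValueError("schedule has no foragers; run identify_foragers first")
    ants = tuple(schedule.ants)
    types = tuple(schedule.foragers)
    if initial is None:
        state = CropState.empty(ants, types)
    else:
        state = initial.copy()
    n = len(schedule.events)
    amounts = np.empty((n + 1, len(ants), len(types)))
    amounts[0] = state.amounts
    for k, event in enumerate(schedule.events):
        if zero_ambiguous and event.ambiguous and not event.is_source_event:
            ev = InteractionEvent(
                event.colony_id, event.time, event.donor, event.recipient,
                0.0, event.ambiguous,
            )
        else:
            ev = event
        _apply_inplace(state, ev, event_index=k)
        amounts[k + 1] = state.amounts
    return ProvenanceTrace(schedule=schedule, ants=ants, types=types, amounts=amounts)
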