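"""Shannon-entropy measures of food blending.

The family of measures quantifies how thoroughly food collected by
different foragers blends as it spreads through the colony:

* types entropy        H_types = H(F)      — partition of all colony food
  among forager-indexed food types; the upper bound on mixing.
* crop entropy         h_mix^a = H(F|A=a)  — blending inside one crop.
* mixing entropy       H_mix = H(F|A)      — load-weighted crop entropy
  over non-foragers; H_mix <= H_types, equality iff perfect blending.
* overall mixing       H_mix^overall       — load-weighted crop entropy
  over all ants; equals P_colony * H_mix when forager crops are pure.

Entropies are computed in nats internally and typically reported
normalized by log|F|, which makes traces comparable across colonies with
different forager counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import ProvenanceTrace

_SUM_TOL = 1e-9


def shannon_entropy(p, base: float | None = None) -> float:
    """Shannon entropy -sum p_i log p_i of a finite distribution.

    ``base=None`` gives nats; ``base=2`` bits.  Zero components contribute
    0 (0·log 0 := 0).  Raises on negative mass or if the masses do not sum
    to 1 within 1e-9.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability mass")
    s = p.sum()
    if abs(s - 1.0) > _SUM_TOL:
        raise ValueError(f"distribution sums to {s!r}, not 1")
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def _entropy_rows(rows: np.ndarray) -> np.ndarray:
    """Row-wise entropy (nats) of non-negative rows, normalizing each row.

    Rows summing to zero get entropy 0 (they never carry weight upstream).
    """
    tot = rows.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, rows / np.where(tot > 0, tot, 1.0), 0.0)
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def types_entropy(trace: ProvenanceTrace, index: int) -> float:
    """H_types at one event index: entropy of P_f over food types (nats)."""
    return shannon_entropy(trace.P_f(index))


def mixing_entropy(trace: ProvenanceTrace, index: int):
    """H_mix at one event index, plus the per-ant crop entropies.

    Returns ``(H_mix, h)`` where ``h`` maps each loaded non-forager ant to
    its crop entropy h_mix^a (nats).  H_mix is the P_a-weighted average of
    the h_mix^a.
    """
    p_fa = trace.P_fa(index)
    p_a = p_fa.sum(axis=1)
    h_rows = _entropy_rows(p_fa)
    labels = trace.nonforager_labels
    h = {a: float(hv) for a, pv, hv in zip(labels, p_a, h_rows) if pv > 0}
    return float((p_a * h_rows).sum()), h


def overall_mixing_entropy(trace: ProvenanceTrace, index: int) -> float:
    """H_mix^overall: crop entropy weighted by P̃_a over all ants (nats)."""
    m = trace.M(index)
    if m <= 0:
        raise ValueError(f"M=0 at index {index}: overall entropy undefined")
    rows = trace.state_after(index)
    p_tilde = rows.sum(axis=1) / m
    return float((p_tilde * _entropy_rows(rows)).sum())


@dataclass
class EntropyTrace:
    """Per-event entropy trajectory of a provenance trace (all in nats).

    ``final_crop_entropies`` covers ants that hold food at the last event;
    ``mean_crop_entropy_norm`` / ``std_crop_entropy_norm`` are their
    unweighted mean and standard deviation normalized by log|F|.
    """

    h_types: np.ndarray
    h_mix: np.ndarray
    ratio: np.ndarray  # H_mix / H_types, NaN where H_types == 0
    p_colony: np.ndarray
    h_overall: np.ndarray
    log_n_types: float
    final_crop_entropies: dict[str, float]
    mean_crop_entropy_norm: float
    std_crop_entropy_norm: float


def entropy_trace(trace: ProvenanceTrace) -> EntropyTrace:
    """Compute the full entropy trajectory along a provenance trace.

    Indices where no food has yet reached a non-forager (Z = 0) report
    H_types = H_mix = 0.
    """
    n = trace.n_events
    h_types = np.zeros(n)
    h_mix = np.zeros(n)
    p_colony = np.zeros(n)
    h_overall = np.zeros(n)
    nf = trace.nonforager_mask
    for k in range(n):
        state = trace.state_after(k)
        m = state.sum()
        if m <= 0:
            continue
        rows_nf = state[nf]
        z = rows_nf.sum()
        p_colony[k] = z / m
        h_all = _entropy_rows(state)
        h_overall[k] = float(((state.sum(axis=1) / m) * h_all).sum())
        if z > 0:
            p_f = rows_nf.sum(axis=0) / z
            pos = p_f[p_f > 0]
            h_types[k] = float(-(pos * np.log(pos)).sum())
            p_a = rows_nf.sum(axis=1) / z
            h_mix[k] = float((p_a * h_all[nf]).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(h_types > 0, h_mix / h_types, np.nan)

    final = {}
    for ant in trace.nonforager_labels:
        try:
            comp = trace.crop_composition(ant, n - 1)
        except ValueError:
            continue
        pos = comp[comp > 0]
        final[ant] = float(-(pos * np.log(pos)).sum())
    log_f = float(np.log(len(trace.types)))
    vals = np.array(list(final.values()))
    mean_norm = float(vals.mean() / log_f) if len(vals) and log_f > 0 else float("nan")
    std_norm = float(vals.std() / log_f) if len(vals) and log_f > 0 else float("nan")
    return EntropyTrace(
        h_types=h_types,
        h_mix=h_mix,
        ratio=ratio,
        p_colony=p_colony,
        h_overall=h_overall,
        log_n_types=log_f,
        final_crop_entropies=final,
        mean_crop_entropy_norm=mean_norm,
        std_crop_entropy_norm=std_norm,
    )


def largest_events_entropy(volumes, n: int) -> float:
    """Entropy (nats) of the ``n`` largest receiving volumes of one ant.

    Each event counts as one component; the ``n`` largest volumes are
    normalized to a distribution.  With the event count taken as the
    number of foragers this statistic approximates the crop entropy an ant
    ends up with, since a crop is dominated by its few largest receipts.
    """
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError("empty receive history")
    top = np.sort(v)[::-1][: max(int(n), 1)]
    tot = top.sum()
    if tot <= 0:
        return 0.0
    return shannon_entropy(top / tot)


def geometric_mix_entropy(delta: float, n: int) -> float:
    """Entropy (nats) of the geometric receipt sequence m_j = δ(1-δ)^{j-1}.

    Models an ant filling up through a series of decreasing receipts, each
    a fraction δ of the remaining free space, truncated at ``n`` events
    (conventionally the number of foragers).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    if n < 1:
        raise ValueError("n must be >= 1")
    j = np.arange(1, n + 1)
    m = delta * (1.0 - delta) ** (j - 1)
    return shannon_entropy(m / m.sum())


def receive_volumes(trace: ProvenanceTrace) -> dict[str, list[float]]:
    """Per-non-forager list of received volumes (source events excluded)."""
    out: dict[str, list[float]] = {a: [] for a in trace.nonforager_labels}
    for ev in trace.schedule.events:
        if not ev.is_source_event and ev.recipient in out and ev.volume > 0:
            out[ev.recipient].append(ev.volume)
    return out
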