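"""The stochastic food-transfer rule and its inference.

The volume an ant passes in an interaction is limited by the maximal
transferable volume ``v_max`` — the minimum of the donor's crop content
and the recipient's free space.  The realized fraction ``ṽ = v / v_max``
follows a truncated exponential on [0, 1]:

    p_δ(ṽ) = c_δ (1/δ) exp(-ṽ/δ),   c_δ = 1 / (1 - exp(-1/δ))

with the single scale parameter δ fitted by maximum likelihood.  The rule
acting on the *fraction* rather than the absolute volume means ants
control relative, capacity-respecting amounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .tracking import ProvenanceTrace

#: Sample mean at/above which the truncated-exponential MLE diverges
#: (the uniform distribution on [0,1] is the δ → ∞ limit).
_UNIFORM_MEAN = 0.5


# ---------------------------------------------------------------------------
# truncated exponential on [0, 1]
# ---------------------------------------------------------------------------

def truncated_exp_norm(delta: float) -> float:
    """Normalizer c_δ = 1/(1 - e^{-1/δ})."""
    return 1.0 / -np.expm1(-1.0 / delta)


def truncated_exp_pdf(v, delta: float) -> np.ndarray:
    """Density c_δ (1/δ) e^{-v/δ} on [0, 1], zero outside."""
    v = np.asarray(v, dtype=float)
    c = truncated_exp_norm(delta)
    out = c / delta * np.exp(-v / delta)
    return np.where((v >= 0) & (v <= 1), out, 0.0)


def truncated_exp_mean(delta: float) -> float:
    """Mean of the truncated exponential: δ - 1/(e^{1/δ} - 1)."""
    x = 1.0 / delta
    if x > 700.0:  # e^x overflows; the correction term is numerically zero
        return float(delta)
    return float(delta - 1.0 / np.expm1(x))


def sample_truncated_exp(delta: float, size, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of ṽ ~ p_δ on [0, 1]."""
    u = rng.random(size)
    return -delta * np.log1p(u * np.expm1(-1.0 / delta))


# ---------------------------------------------------------------------------
# per-event transfer potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferPotential:
    """Geometry of one ant-to-ant event relative to crop capacities.

    ``d`` and ``r`` are donor and recipient loads as fractions of their
    capacities; ``p = d (1 - r)`` is the volume potential used as the
    binning covariate; ``v_max`` is the operational transfer ceiling and
    ``v_tilde = v / v_max`` the realized fraction.
    """

    event_index: int
    donor: str
    recipient: str
    d: float
    r: float
    p: float
    v_max: float
    v: float
    v_tilde: float
    clipped: bool = False
    forager_donor: bool = False
    forager_recipient: bool = False


@dataclass
class FractionRecords:
    """Transfer-potential records plus bookkeeping of excluded events."""

    records: list[TransferPotential]
    n_vmax_zero: int = 0
    n_missing_capacity: int = 0

    def v_tilde(self) -> np.ndarray:
        return np.array([r.v_tilde for r in self.records])


def compute_transfer_fractions(
    trace: ProvenanceTrace, capacities: dict[str, float]
) -> FractionRecords:
    """Compute ṽ, d, r, p for every ant-to-ant event of a trace.

    Events with ``v_max = 0`` (empty donor or full recipient) are excluded
    and counted; events missing a capacity for either participant are
    skipped with a warning count.  ṽ above 1 within float tolerance is
    clipped to 1 and flagged.
    """
    loads = trace.loads()
    idx = trace._index
    foragers = set(trace.schedule.foragers)
    recs: list[TransferPotential] = []
    n_zero = 0
    n_missing = 0
    for k, ev in enumerate(trace.schedule.events):
        if ev.is_source_event:
            continue
        cap_d = capacities.get(ev.donor)
        cap_r = capacities.get(ev.recipient)
        if not cap_d or not cap_r:
            n_missing += 1
            continue
        load_d = loads[k, idx[ev.donor]]
        load_r = loads[k, idx[ev.recipient]]
        v_max = min(load_d, max(cap_r - load_r, 0.0))
        if v_max <= 0:
            n_zero += 1
            continue
        vt = ev.volume / v_max
        clipped = vt > 1.0
        recs.append(
            TransferPotential(
                event_index=k,
                donor=ev.donor,
                recipient=ev.recipient,
                d=min(load_d / cap_d, 1.0),
                r=min(load_r / cap_r, 1.0),
                p=min(load_d / cap_d, 1.0) * (1.0 - min(load_r / cap_r, 1.0)),
                v_max=v_max,
                v=ev.volume,
                v_tilde=min(vt, 1.0),
                clipped=clipped,
                forager_donor=ev.donor in foragers,
                forager_recipient=ev.recipient in foragers,
            )
        )
    if n_missing:
        warnings.warn(f"{n_missing} events skipped: missing capacity", stacklevel=2)
    return FractionRecords(records=recs, n_vmax_zero=n_zero, n_missing_capacity=n_missing)


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class TransferRuleFit:
    """Fitted truncated-exponential transfer rule.

    ``delta`` is the MLE scale; ``unbounded=True`` flags samples whose mean
    reaches the uniform limit (mean >= 0.5), where the likelihood has no
    finite maximizer.  ``n_zero`` counts ṽ = 0 events excluded as
    non-transfers.
    """

    delta: float
    n: int
    n_zero: int = 0
    unbounded: bool = False
    degenerate: bool = False
    log_likelihood: float = float("nan")
    r_squared: float = float("nan")
    bins: list["TransferRuleFit"] = field(default_factory=list)
    bin_edges: np.ndarray | None = None
    bin_counts: list[int] = field(default_factory=list)

    @property
    def c_delta(self) -> float:
        return truncated_exp_norm(self.delta)


def _loglik(delta: float, v: np.ndarray) -> float:
    n = v.size
    return n * np.log(truncated_exp_norm(delta)) - n * np.log(delta) - v.sum() / delta


def fit_delta_mle(v_tilde, delta_max: float = 50.0) -> TransferRuleFit:
    """Fit δ by maximum likelihood from a sample of realized fractions ṽ.

    The MLE solves ``mean(ṽ) = δ - 1/(e^{1/δ} - 1)`` (the truncated-
    exponential mean), found by bracketed root-finding.  ṽ = 0 events are
    excluded as non-transfers and counted in ``n_zero``; a sample mean at
    or above 0.5 has no finite MLE (uniform limit) and is flagged
    ``unbounded``; an all-zero sample is flagged ``degenerate``.
    """
    v = np.asarray(list(v_tilde), dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if ((v < 0) | (v > 1)).any():
        raise ValueError("v_tilde values must lie in [0, 1]")
    n_zero = int((v == 0).sum())
    v = v[v > 0]
    if v.size == 0:
        return TransferRuleFit(delta=float("nan"), n=0, n_zero=n_zero, degenerate=True)
    if v.size < 2:
        raise ValueError("need at least 2 nonzero samples")
    m = v.mean()
    if m >= _UNIFORM_MEAN:
        return TransferRuleFit(
            delta=float("inf"), n=v.size, n_zero=n_zero, unbounded=True,
            log_likelihood=0.0,
        )
    delta = float(
        optimize.brentq(lambda d: truncated_exp_mean(d) - m, 1e-8, delta_max)
    )
    return TransferRuleFit(
        delta=delta, n=v.size, n_zero=n_zero, log_likelihood=_loglik(delta, v)
    )


def _histogram_r2(v: np.ndarray, delta: float, n_bins: int = 10) -> float:
    """R² of the fitted density against an empirical histogram density."""
    dens, edges = np.histogram(v, bins=n_bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pred = truncated_exp_pdf(centers, delta)
    ss_res = float(((dens - pred) ** 2).sum())
    ss_tot = float(((dens - dens.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def binned_rule_fit(
    records: FractionRecords | list[TransferPotential],
    bin_edges=(0.0, 0.25, 0.5, 0.75, 1.0),
    min_bin_size: int = 30,
) -> TransferRuleFit:
    """Fit δ per bin of the volume potential p = d(1 - r).

    Returns the pooled fit with per-bin fits attached (``.bins``); bins
    below ``min_bin_size`` are flagged (NaN delta), not fitted.  An
    approximately p-independent δ across bins indicates that ants control
    the transferred *fraction* rather than absolute volume.
    """
    recs = records.records if isinstance(records, FractionRecords) else list(records)
    edges = np.asarray(bin_edges, dtype=float)
    p = np.array([r.p for r in recs])
    v = np.array([r.v_tilde for r in recs])
    pooled = fit_delta_mle(v)
    if not pooled.unbounded and not pooled.degenerate:
        pooled.r_squared = _histogram_r2(v[v > 0], pooled.delta)
    pooled.bin_edges = edges
    which = np.clip(np.digitize(p, edges[1:-1]), 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        vb = v[which == b]
        nb = int((vb > 0).sum())
        pooled.bin_counts.append(int(vb.size))
        if nb < min_bin_size:
            pooled.bins.append(
                TransferRuleFit(delta=float("nan"), n=nb, degenerate=True)
            )
            continue
        fit = fit_delta_mle(vb)
        if not fit.unbounded:
            fit.r_squared = _histogram_r2(vb[vb > 0], fit.delta)
        pooled.bins.append(fit)
    return pooled


# ---------------------------------------------------------------------------
# direction statistics
# ---------------------------------------------------------------------------

@dataclass
class DirectionalityStats:
    """Who-donates summaries, split by participant class.

    Forager/non-forager events: fractions where the forager donated,
    received, or the event was ambiguous (volume at or below the detection
    threshold ε, in fraction-of-capacity units).  Non-forager pairs:
    fraction where the relatively fuller ant (load / own capacity) donated,
    and separately where the absolutely fuller ant donated; ties and
    ambiguous events are excluded from those denominators.
    """

    n_forager_events: int
    forager_donor_fraction: float
    forager_recipient_fraction: float
    forager_ambiguous_fraction: float
    n_nonforager_events: int
    fuller_donates_fraction: float
    absolute_fuller_donates_fraction: float
    nonforager_ambiguous_fraction: float


def directionality_stats(
    trace: ProvenanceTrace,
    capacities: dict[str, float],
    epsilon: float = 0.01,
) -> DirectionalityStats:
    """Direction-of-transfer statistics over all ant-to-ant events.

    ``epsilon`` is the detection threshold: events whose volume is at most
    ``epsilon * min(capacities of the pair)`` count as ambiguous.
    """
    loads = trace.loads()
    idx = trace._index
    foragers = set(trace.schedule.foragers)
    nf_total = nf_fuller = nf_abs_fuller = nf_decided = nf_abs_decided = 0
    nf_ambig = 0
    f_total = f_donor = f_recip = f_ambig = 0
    for k, ev in enumerate(trace.schedule.events):
        if ev.is_source_event:
            continue
        cap_d = capacities.get(ev.donor, 1.0)
        cap_r = capacities.get(ev.recipient, 1.0)
        ambiguous = ev.ambiguous or ev.volume <= epsilon * min(cap_d, cap_r)
        d_forg = ev.donor in foragers
        r_forg = ev.recipient in foragers
        if d_forg or r_forg:
            f_total += 1
            if ambiguous:
                f_ambig += 1
            elif d_forg:
                f_donor += 1
            else:
                f_recip += 1
        else:
            nf_total += 1
            if ambiguous:
                nf_ambig += 1
                continue
            load_d = loads[k, idx[ev.donor]]
            load_r = loads[k, idx[ev.recipient]]
            rel_d, rel_r = load_d / cap_d, load_r / cap_r
            if rel_d != rel_r:
                nf_decided += 1
                nf_fuller += rel_d > rel_r
            if load_d != load_r:
                nf_abs_decided += 1
                nf_abs_fuller += load_d > load_r
    return DirectionalityStats(
        n_forager_events=f_total,
        forager_donor_fraction=f_donor / f_total if f_total else float("nan"),
        forager_recipient_fraction=f_recip / f_total if f_total else float("nan"),
        forager_ambiguous_fraction=f_ambig / f_total if f_total else float("nan"),
        n_nonforager_events=nf_total,
        fuller_donates_fraction=nf_fuller / nf_decided if nf_decided else float("nan"),
        absolute_fuller_donates_fraction=(
            nf_abs_fuller / nf_abs_decided if nf_abs_decided else float("nan")
        ),
        nonforager_ambiguous_fraction=nf_ambig / nf_total if nf_total else float("nan"),
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
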