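# Methods

This note records the models implemented in `trophamix`, the assumptions
behind them, the defaults and why they were chosen, and the places where
the design was genuinely open.

## Provenance tracking

Food is partitioned into "types" indexed by the forager that first
collected it at the source, so a colony with |F| foragers has |F| types.
The tracker assumes mixing inside a crop is instantaneous relative to the
rate of interactions, so a crop is fully described by a vector of type
amounts with no internal structure. Each ant-to-ant event of volume *v*
moves the fraction *v/V_donor* of the donor's crop, type by type; source
events add pure own-type food to a forager's crop (additively — nothing
suggests a forager empties before reloading). Totals are conserved
exactly except at source events, which add their volume. The absolute
volume unit is arbitrary and cancels in every probability, so schedules
may be recorded in any consistent unit.

Numerics: amounts are float64; negative dust below `1e-9 · M` (M = total
food) is clamped to zero, anything larger raises an infeasibility error
naming the event. A transfer exceeding the donor's content beyond the
same tolerance is an error, not a clamp: it indicates a corrupted
schedule rather than round-off.

Distribution conventions: `Z` and everything normalized by it (`P_a`,
`P_{f,a}`, `P_f`) run over non-forager ants only; `M` and
`P_colony = Z/M` run over all ants. Direction-ambiguous events are
applied as recorded by default; a switch treats them as zero-volume
contacts instead, since they sit below the detection threshold anyway.

## Entropy measures

All entropies are computed in nats and reported normalized by log|F|
where cross-colony comparability matters; bits are used only for the
two-source intuition (1 bit = perfect 1:1 blend; 0.81 bit ≈ a 3:1 crop).
The mixing entropy `H_mix = Σ_a P_a h_mix^a` is a conditional entropy, so
`H_mix ≤ H_types` always, with equality only when every crop matches the
colony-wide type distribution. The unweighted mean and spread of crop
entropies cover ants holding food — the entropy of an empty crop is
undefined. When several colonies are averaged, each is normalized by its
own log|F| first.

Two reduced statistics approximate a crop entropy without tracking:
the entropy of an ant's *n* largest receiving volumes (n = |F| by
default), motivated by crops being dominated by a few large events; and
the entropy of the geometric sequence `m_j = δ(1−δ)^{j−1}`, the expected
receipt cascade of an ant that repeatedly fills a fraction δ of its
remaining free space. Both take δ and n as parameters; nothing is
hard-coded since fitted scales differ between data subsets.

## Transfer-rule inference

For every ant-to-ant event, `v_max = min(donor content, recipient free
space)` and `ṽ = v/v_max`. The fullness product `p = d(1−r)` is computed
alongside but used only as a binning covariate; `v_max` is the
operational ceiling. Events with `v_max = 0` are excluded and counted;
ṽ marginally above 1 (float noise) is clipped and flagged.

The truncated exponential `p_δ(ṽ) = c_δ (1/δ) e^{−ṽ/δ}` on [0, 1] has
mean `δ − 1/(e^{1/δ} − 1)`, which is strictly increasing in δ with
supremum 1/2 (the uniform limit). The MLE therefore reduces to matching
the sample mean, solved by bracketed root-finding on δ ∈ (0, 50]; samples
with mean ≥ 1/2 are flagged unbounded rather than assigned an arbitrary
large δ. ṽ = 0 events are excluded as non-transfers (they are ambiguous
contacts, not realized volumes) and reported separately. Per-bin fits
(default edges 0, 0.25, 0.5, 0.75, 1 over p; minimum 30 events per bin)
report δ and an R² of the fitted density against a 10-bin histogram —
agreement across bins is the evidence that ants control fractions rather
than absolute volumes.

Directionality statistics use a detection threshold ε (default 0.01 in
fraction-of-capacity units): events at or below it count as ambiguous.
For non-forager pairs the "fuller donates" fraction is computed both for
relative (load/capacity) and absolute loads, ties excluded. All of these
statistics are invariant to a uniform rescaling of volumes and
capacities.

Crop capacities: when a schedule does not carry measured capacities, the
package estimates capacity as the maximum load ever observed — an
explicit lower bound, reported as such. Underestimated capacities
understate free space and so inflate ṽ and δ̂; analyses on synthetic
colonies therefore use the generator's true capacities, which the CLI
exchanges via an `ant,capacity` CSV.

## Hybrid simulations

Each simulation keeps the recorded pair sequence (and all source events)
and substitutes the interaction rule: stochastic truncated-exponential
volumes with uniformly random direction; maximal mixing (pool and split
equally — capacities deliberately ignored, as the point is an upper bound
set by the schedule alone); maximal transfer (recorded donor gives
v_max); and no-secondary (only forager-donor events transfer, using the
stochastic rule). Under the stochastic rule a drawn event with
`v_max = 0` simply transfers nothing; the direction is not re-drawn.
Recorded direction is kept wherever the rule does not randomize it.
Ensembles use one generator per replicate, seeded `base_seed + r`.
Identity shuffling permutes all ant-label slots of ant-to-ant events
uniformly (preserving each ant's slot count), resolving self-pairings by
random swaps.

## The δ̃ trade-off model

The model strips the system to its essential tension: equal capacities,
random interactions with the empirical forager/non-forager event ratio
(713:1357), and a deterministic rule `v = δ̃ · v_max`. Foragers start
holding all food they will ever deliver (M/n_foragers each, own pure
type) and never receive, so M is conserved and
`H_mix^overall = P_colony · H_mix` holds exactly at every step. Foragers
act as reservoirs: their initial holding may exceed the common capacity,
which binds recipients only. Defaults: 70 ants, 5 foragers, capacity 1,
M = half the aggregate non-forager capacity (a colony that can absorb
everything comfortably), 20 interactions per ant → 700 events.

The across-ant spread of crop entropies is computed over loaded
non-forager crops. Forager crops are pure by construction (entropy 0),
so including them would make the statistic bimodal and track satiation
rather than mixing uniformity; with the non-forager definition the
spread is smallest near δ̃ ≈ 0.26 and largest as δ̃ → 1.

Sweeps reuse the same replicate seeds at every grid point (common random
numbers), so endpoint curves vary smoothly in δ̃ instead of carrying
independent Monte-Carlo noise per point.

## Synthetic colonies

The generator emulates a famine-relief experiment: empty crops at start;
foragers reload at the source whenever their crop drops below 20% of
capacity (filling up, unless a fixed trip volume is configured);
ant-to-ant events drawn with the empirical forager-event fraction, with
early non-forager events falling back to forager events while no worker
holds food; volumes `ṽ · v_max` with ṽ drawn from the rule by inverse
CDF. Defaults mirror the experimental colonies: 70 ants, 5 foragers,
δ = 0.26, 700 trophallactic events, constant unit capacity (lognormal
heterogeneity available — needed for the maximal-transfer regime not to
collapse to pure relaying). Its bookkeeping is an independent, dict-based
implementation of the provenance arithmetic, which makes exact agreement
with the tracker a meaningful integration oracle rather than a tautology.

What the generator does not emulate: spatial structure and encounter
kinetics (partners are chosen uniformly), interaction durations,
forager-recipient events (its foragers only donate, so the
forager-donates fraction runs above the empirical 0.76), brood, and
multiple food sources. Passing tests on synthetic colonies therefore
validate the bookkeeping, the estimators and the simulation machinery —
not claims about any particular real colony.

## Problem sizes

Default analyses and the reproduction script use the generator defaults
(700 events, 70 ants), 30-replicate ensembles, a 20-point δ̃ grid with 30
replicates per point, and 30×2000-sample parameter-recovery batches —
the sizes at which the corresponding empirical analyses operate, and
comfortably reproducible on a laptop in well under a minute each.

## Known limitations

* Greedy modularity maximization is a heuristic; community counts and Q
  are stable for a fixed input but are not guaranteed optima, so they are
  compared with tolerance while transitivity is exact. The "performance"
  partition-quality figure is informational: the conventional correctly-
  classified-pairs measure.
* Max-observed-load capacity estimation biases δ̂ upward on data without
  measured capacities (see above).
* The tracker stores the full per-event crop tensor
  (events × ants × types); for schedules orders of magnitude longer than
  the experimental ones a streaming variant would be preferable.
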