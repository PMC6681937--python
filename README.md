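# trophamix

Quantitative analysis of food sharing in ant colonies by mouth-to-mouth
transfer (trophallaxis). Most colony members never leave the nest: a
handful of foragers collect liquid food and pass it inward, where it is
stored in crops ("social stomachs") of finite capacity and repeatedly
re-shared. `trophamix` labels food by the forager that first collected it
and follows these "food types" through a time-ordered interaction
schedule, asking how thoroughly the colony blends them — and what limits
that blending.

The package is aimed at researchers in collective animal behavior and
network science who have (or want to simulate) per-interaction records of
who gave food to whom, when, and how much.

## The quantities at the core

Provenance tracking assumes food mixes instantly inside a crop, so each
transfer of volume *v* moves a proportional slice of the donor's
composition, type by type:

    n'_recv(f) = n_recv(f) + (v / V_donor) · n_donor(f)

With `P_f` the colony-wide share of type *f* and `P(f|a)` the mixture in
ant *a*'s crop, blending is scored with Shannon entropies:

* **types entropy** `H_types = −Σ_f P_f log P_f` — how evenly the foragers
  contributed; the ceiling on mixing.
* **crop entropy** `h_mix^a = −Σ_f P(f|a) log P(f|a)` — blending inside one
  crop.
* **mixing entropy** `H_mix = Σ_a P_a · h_mix^a` — load-weighted crop
  entropy over non-foragers; `H_mix ≤ H_types`, with equality only under
  perfect blending.
* **overall mixing** `H_mix^overall = P_colony · H_mix`, where `P_colony`
  is the fraction of all food already inside non-forager crops (the
  colony's satiation level).

Transfers obey a stochastic rule: the realized fraction `ṽ = v / v_max`
of the maximal transferable volume (donor content vs. recipient free
space) follows a truncated exponential on [0, 1],

    p_δ(ṽ) = c_δ (1/δ) e^{−ṽ/δ},   c_δ = 1/(1 − e^{−1/δ}),

whose scale δ is fitted by maximum likelihood. Hybrid simulations replay
the empirical schedule under substituted rules (maximal mixing, maximal
transfer, no secondary sharing, stochastic rule), and a minimal
"δ̃ model" exposes the trade-off between fast food accumulation and
thorough mixing.

## Worked example

Everything below runs on a synthetic colony with known ground truth
(70 ants, 5 foragers, δ = 0.26, ~700 interactions, empty crops at start):

```
$ trophamix generate --seed 1 --out colony.csv --capacities-out caps.csv
wrote 737 events to colony.csv

$ trophamix entropy colony.csv --out entropy.csv
final H_mix/H_types = 0.794; mean crop entropy = 0.783 log|F|

$ trophamix rule-fit colony.csv --capacities caps.csv
delta (MLE) = 0.2631 on n = 700 transfers
mean v_tilde = 0.2403
per-bin delta = [0.251, 0.263, 0.317, 0.286]
forager donates: 0.922 of N=244
fuller donates: 0.596 of N=456

$ trophamix network colony.csv
70 nodes, 569 edges, 3 communities, Q = 0.131, transitivity = 0.271,
intra/inter = 279/290
```

Reading the output: food reaches essentially every ant, yet the colony
levels off at ~79% of the blending ceiling — crops stay individual
mixtures rather than converging to one communal blend. The fitted
δ ≈ 0.26 says a transfer typically realizes only a quarter of its
potential volume, and the per-bin fits show δ does not depend on how
full the pair is: ants control *fractions*, not absolute volumes. The
near-1 intra/inter edge ratio and low modularity say the contact network
itself poses no barrier to mixing — the transfer rule, not the who-meets-
whom structure, is what keeps blending partial.

The same library calls are available in Python (`generate_colony`,
`track_provenance`, `entropy_trace`, `fit_delta_mle`, `run_ensemble`,
`sweep_delta`, ...), and `trophamix run --synthetic --outdir bundle/`
produces the full report bundle in one go.

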