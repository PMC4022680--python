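# Methods

## Model overview

`fissim` simulates the dissolution of an animal social group as a feedback
loop between two processes:

1. **Daily foraging assignment.** Each individual chooses, once per day and
   in a random order, between staying at rest and moving to one of two
   resource patches. The per-draw probability of moving to patch *s* is
   `P_i,s = λ_i,s + C · Σ_{k in s} w(i,k)`: an intrinsic nutritional term
   plus a mimetic term proportional to the grooming time the individual
   directs at those already in the patch. The draw is resolved by a single
   uniform number x with stacked, inclusive thresholds (x ≤ P₁ → patch 1;
   P₁ < x ≤ P₁+P₂ → patch 2; otherwise rest). Probabilities are recomputed
   after every departure, so early movers pull later ones.
2. **Network rewiring.** On days when the whole group forages split across
   both patches (a *temporary fission*), every individual moves T% of each
   link toward the other subgroup onto its same-subgroup companions, in
   equal shares. Weight is conserved exactly: each row of the network always
   sums to 100 (% of that individual's social time).

The simulation stops on the first day whose post-update network satisfies the
irreversible-fission criterion — both subgroups ≥ 4 individuals (a split
shedding ≤ 3 animals is a dispersion, not a fission) and every individual
placing ≥ 95% (inclusive) of its social time within its own subgroup — or is
right-censored at 900 days, the empirical upper bound for observed fissions.
Events between 90 and 900 days are additionally flagged *viable*, matching
the range reported for wild primate groups; viability is a classification,
never a stopping rule.

## Parameters

| parameter | meaning | units | default / design values |
|---|---|---|---|
| `n` | group size | individuals | 10, 20 |
| `C` | mimetic coefficient | probability per unit link weight | 0.001–0.009 |
| `lambda1`, `lambda2` | mean intrinsic per-day move probabilities | probability/day | 0.05–0.45 (equal pairs) |
| `transfer` (T) | social-time transfer per temporary fission | % of each cross link | 10–100 |
| `max_days` | censoring horizon | days | 900 |
| `threshold` | within-subgroup social-time criterion | % | 95 (inclusive) |
| `min_subgroup` | smallest subgroup that counts as fission | individuals | 4 |

The design couples C and λ so that λ₁+λ₂ = 1 − 100·C exactly; the
**Nutrition/Sociality ratio** R = (λ₁+λ₂)/(100·C) then spans 0.11–9. The
equality is not incidental: since all links sum to 100, it makes
P₁+P₂ = 1 for an individual facing a fully assembled group, which is what
allows a mimetic chain to capture every member on fully social days.

## Interpretation decisions

The verbal description of this class of model underdetermines the day
process, and the choices below were selected because they are the ones that
reproduce the reported regime structure (no fission at 10% transfer; no
fission at the lowest ratio; the 50%/70% transfer thresholds for
ratio < 1.5 at n = 10/20). The alternatives remain available as options and
are exercised by the test suite.

**One movement opportunity per individual per day** (`day_mode="single_pass"`,
default). λ is then literally a per-day probability, and a group of
cohesion-driven animals (small λ, large C) usually fails to empty the
resting area — it simply stays together. The alternative
(`day_mode="until_empty"`) repeats the pass with fresh draws until everyone
has moved; it forces a full two-area split nearly every day at every
parameter setting, which makes even the most cohesive conditions fission
rapidly at high transfer — qualitatively wrong for a model whose point is
that cohesive groups do not split.

**Rewiring only on full-foraging days.** The network update is defined for
the moment when all individuals have moved; days on which part of the group
rests leave the network untouched. This is what protects low-ratio groups:
their rare excursions involve a few individuals and never rewire the network.

**Persistent heterogeneous needs** (`preference="uniform"`, default). Each
individual's total drive λ₁+λ₂ is split between the patches as
λ_i,1 = 2λ₁u, λ_i,2 = 2λ₂(1−u) with u ~ U(0,1) drawn once per simulation —
a maximum-entropy reading of "each individual is attributed an intrinsic
probability for each resource area", kept as a persistent state variable.
Without heterogeneity (option `preference="homogeneous"`) subgroup
composition is pure noise and nutritional needs cannot shape the split,
removing the mechanism by which need-driven groups (high R) sort into
consistent subgroups. `redraw_daily=True` resamples the split every day,
which destroys that sorting; it exists for sensitivity analysis.

**Mimetic links are the mover's outgoing weights** in both the movement
probability and the rewiring rule (the notation r(k,i) is directionally
ambiguous); `move_probabilities(..., direction="incoming")` exposes the
other reading.

**Dispersion-sized splits still rewire.** A complete two-area day with a
subgroup of ≤ 3 cannot end the simulation but does transfer social time:
the size floor is part of the fission definition, not of the social
dynamics.

**Check after update.** The criterion is evaluated against the current day's
partition on the network *after* that day's transfer (move → rewire →
check): irreversibility is a property of the realised subgrouping together
with the network it produces.

## Numerical choices

- Row sums are validated to an absolute tolerance of 1e−9; the update is
  exactly conservative in exact arithmetic, so no renormalisation is
  applied (none is needed: 200 days of rewiring drift row sums by ~1e−14).
- The batch engine is a numba kernel that duplicates, operation for
  operation, the pure-Python reference path (`backend="python"`); the test
  suite replays kernel-recorded day traces through the Python network
  operations and checks the fission day and final network agree. The two
  backends consume different random streams, so per-seed results differ
  between them while each is individually reproducible.
- Replicate r of condition c in a batch uses
  `SeedSequence([base_seed, c, r])` reduced below 2³¹, so any single
  replicate can be replayed in isolation and a `RunManifest` (base seed +
  grid) reproduces a batch bit-for-bit.
- Visiting order within a day is a fresh Fisher–Yates permutation; no fixed
  order biases the mimetic pull.
- Dunn's pairwise test uses the standard rank-sum z with mid-rank tie
  correction; the multiple-comparison adjustment defaults to none (with
  Bonferroni/Holm options), and homogeneity groups are connected components
  of the non-significant relation at α = 0.05.
- A flat mean-days response defines a null regression (r² = 0, F = 0)
  rather than NaN.

## What the generator does and does not emulate

The simulated data reproduce, at 100 replicates per condition (the original
sampling effort was 1 000; 100 keeps the full two-size grid under a minute
and leaves Monte-Carlo error well below the effect sizes under test):

- exact conservation of each individual's 100-unit social-time budget;
- the nine designed Nutrition/Sociality ratios;
- no fission anywhere at 10% transfer;
- near-total protection of the lowest ratio (0.11): zero fissions at
  n = 20 across all transfers, and at n = 10 a residual ~5% of replicates
  fission at 100% transfer only — the one leak this implementation has
  relative to the reported absolute zero;
- fission thresholds for ratio < 1.5 of 50–60% transfer at n = 10 and
  80–100% at n = 20 (at or above the reported 50%/70% floors);
- mean days-to-fission non-increasing in transfer at every ratio, and a
  strongly negative pooled slope.

It does **not** reproduce two reported patterns. First, the pooled
mean-days-vs-transfer profile is sigmoidal rather than near-linear (r² ≈
0.67–0.68 versus a reported 0.97): under this day-process reading, fission
onset concentrates at transfer ≥ 50% for every ratio, whereas a near-linear
decline requires high-ratio conditions to fission slowly from ~20–30%
transfer. Second, and relatedly, the speed ranking across ratio bands is
compressed: the middle band (0.43–2.33) is not reliably faster than the
high band (> 2.33), so the U-shaped response and the positive
ratio/negative group-size regression signs are not recovered. Every
day-process variant we tested that fixes these two patterns breaks the
hard zero-fission facts (10% transfer, ratio 0.11, the 50%/70% thresholds),
which we prioritised as the less ambiguous claims. The corresponding
acceptance tests assert the reported directions and are expected to fail;
they are kept failing rather than weakened.

Beyond the study design, the usual caveats of the model family apply: an
egalitarian seed network (no kinship, rank or preferred associations),
exactly two identical patches with no depletion or competition, a single
group-wide transfer percentage, and one potential temporary fission per
day. Real fission times emerge from all of these at once, so agreement on
the simulated grid says nothing about forecasting any particular wild
group.

## Limitations

- The day process and preference scheme are interpretations chosen against
  reported aggregate outcomes (see above); the original implementation is
  not available for instruction-level comparison.
- The irreversible-fission criterion requires the *current* day's partition
  to align with the clustered network; a network that is 95%-clusterable
  along a bipartition nobody realises that day does not end the run.
- Censored runs are recorded at 900 days; analyses choose between capping
  and excluding them, and conclusions near the censoring boundary depend on
  that choice.
- Custom seed networks can be imported (`fissim.io.read_network`), but no
  generators for random or empirical network topologies are provided.
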