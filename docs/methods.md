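# Methods

This note records the models, parameter choices and numerical decisions
behind `medalloc`, and what the synthetic-data tests do and do not
demonstrate about real hospital networks.

## Forest MDP for share/idle decisions

The model is the standard forest-management MDP with `S` age states
(default 3, matching the three-stage recommendation tables) and two
actions. Under *Wait*, state `s` moves to `min(s+1, S)` unless a
disruption resets it to state 1, which happens with probability `p`;
the reward is 0 except `r1` in the oldest state. Under *Cut*, the state
resets to 1 with certainty; the reward is 0 in state 1, 1 in the middle
states and `r2` in the oldest. PSAF inputs map onto the model as
`(p, r1, r2)` = (hospitalization ratio, clinical severity,
transmissibility): resets become more likely as more cases hospitalize,
and the terminal rewards grow with pandemic impact. This mapping is the
one under which the solved model reproduces the published six-scenario
value table cell for cell; it is a modeling identification, not a causal
claim.

Two exact solvers are provided. Policy iteration evaluates each policy
by a direct linear solve of `(I − γ P_π) V = R_π` and improves greedily;
value iteration runs successive approximation to sup-norm tolerance
1e−12. They are implemented independently and required to agree to 1e−6
(with Bellman residual below 1e−9) on randomized models — a test-suite
invariant, not a runtime coupling. Greedy ties break toward *Wait*
(Idle), the conservative action; ties are measure-zero in the inputs.

The **discount factor defaults to 0.5**. It is a config knob, but 0.5 is
the unique value at which all eighteen published stage values satisfy
the Bellman optimality equations, so it is the package's reference
condition. One published cell (scenario 5, stage 2) prints the value of
the Cut action (1.05 = 1 + 0.5·V(1)) with an "Idle" label; the solver
reports Share there, and the tests treat the printed label as a typo
while matching the value.

Display rounding is round-half-even applied to the exact decimal value
(solver noise cleared at 10 dp first). Several solved values land
exactly on a half (2.835, 5.985, 2.625, 9.625) and the reference tables
round them to even (2.84, 5.98, 2.62, 9.62) — the convention of R's
`round`. Plain float `round` would misround values whose binary
representation sits a hair below the half.

The *Ask* action (negative value states) cannot arise under the default
reward parameterization, whose rewards are all non-negative; it is
implemented for reward-shifted models (subtracting `k` from all rewards
shifts every value by `k/(1−γ)`), and the Outlier event label fires when
all three PSAF inputs reach their extreme thresholds (0.9, 7, 5;
configurable).

## Genetic-algorithm engine

One engine serves both encodings. Per generation: rank-proportional
selection → crossover → one-gene mutation → elitist replacement.

- **Selection** is rank-proportional: probability ∝ 1-based fitness
  rank, with average ranks on ties, so a two-individual population is
  sampled 2:1 and an all-equal population uniformly. Rank selection is
  invariant to monotone fitness rescaling, which matters because FF3
  fitness spans eight orders of magnitude between normalized and raw
  attributes.
- **Crossover**: single-point for bit strings; order crossover (OX) for
  permutations, keeping a parent-1 slice and filling remaining positions
  left-to-right in parent-2 order. Crossover probability defaults to 0.8
  (unspecified upstream; a conventional GA default).
- **Mutation** is a per-offspring event (probability 0.5 for allocation,
  0.2 for routing) that changes exactly one gene: a single bit flip or a
  single position swap — not independent per-locus flips.
- **Elitism** defaults to ⌈5% of the population⌉, making the
  best-fitness history monotone (asserted in tests).
- **Stopping**: `patience` generations without best-fitness improvement
  (250 for allocation, per the "maximum iterations without improvement"
  convention) or the hard `max_iterations` cap (1000 allocation, 5000
  routing).
- **Reproducibility**: a single `numpy.random.Generator` seeded from the
  config is threaded through every stochastic step; identical configs
  give bitwise-identical results. A non-finite fitness raises
  immediately, naming the offending chromosome.

## Allocation mechanics

The published method does not state how granting a bed feeds back into
the inputs beyond "getting new beds increases beds, which increases
cost". The package's mechanics: each granted hospital gains `bed_delta`
beds (default 1) and `bed_delta × cost_per_bed` cost, with
`cost_per_bed` defaulting to the hospital's current cost/beds ratio and
the budget defaulting to 10% of fleet beds; exceeding the budget incurs
a hard penalty proportional to the excess (slope 1e9, far above any
feasible fleet fitness on 0–100-scale inputs). All three are exposed.
Reported FF1/FF2 values are evaluated at pre-increment conditions, since
they describe current readiness. A zero death rate violates FF2's
domain; the reader rejects such rows rather than silently adding an
epsilon.

The weights behind the published readiness table are unstated;
`derive_effective_constants` recovers the effective pair
(a, c) = (α/β, 1/γ) by an exact 2×2 solve from any two rows (singular
if the rows are proportional). Fitted from the two best-conditioned
rows, a ≈ 1.826 and c ≈ 23.50 reproduce three further printed cells at
1 dp; a few remaining rows deviate by up to ~0.2, consistent with the
published inputs themselves being rounded to 1 dp.

## Routing

Distances are haversine great-circle kilometres on the WGS84 mean
radius (6371.0088 km). No road network is modelled — published route
maps draw straight legs across water — so tours are geodesic polygons.
Tours are closed and anchored at the first listed location; the GA
searches permutations of the rest, which removes the rotational
degeneracy of closed tours.

FF3's printed form is ambiguous about aggregation over a multi-leg
route. The default is per-leg summation over destinations
(`Σ patients_j / (recovery_cost_j · d_ij · rating_j)`), which makes the
score depend on which legs reach which destinations; an aggregate
variant (`Σpatients / (Σcost · total_distance · Σrating)`) is available,
as is moving the rating to the numerator for policies that prioritize
high-rated destinations. Rating stays in the denominator by default:
needier, lower-rated facilities are prioritized.

With `normalize` set, the FF3 attribute columns are min-max scaled to
[0, 1] before evaluation (distances never are; FF4 is distance-only).
Because min-max maps each column minimum to exactly 0, denominator
attributes are floored at 1e−3 after scaling as a division guard;
without it the minimum-cost location would carry infinite fitness. On
real-scale attributes (patients in the thousands, recovery costs in the
hundreds of thousands) unnormalized per-leg FF3 is of order 1e−8, versus
order 1 normalized — the package asserts the direction of this effect,
not the magnitudes, which depend on the underlying data.

K-means runs on raw (latitude, longitude) pairs via scikit-learn
(k-means++ seeding, 10 restarts, seeded). At the ~40° latitudes of the
contiguous US the metric distortion of treating degrees as planar is
modest and irrelevant to well-separated regional blobs. The elbow rule
picks the k in 2..k_max−1 maximizing the second difference of **log**
SSE. The raw-SSE second difference was considered and rejected: because
absolute SSE drops are largest at small k, that statistic picks k = 2
for essentially any blob geometry (for four equal blobs at rectangle
corners it provably cannot return 4); the log form measures relative
curvature and recovers the true count for well-separated blobs.
Singleton clusters yield no tour and are excluded (with a warning) from
the average regional fitness.

## Synthetic networks

The generator emulates the *shape* of US facility registries: ratings
1–5 from a configurable distribution (default mode at 3–4 stars), beds
log-uniform in 16–69, death-rate scores uniform in 10–45, cost scores
uniform in 49–78 — the magnitudes of the published, already-normalized
readiness table — patient loads uniform in 0–5000, and coordinates
uniform in a Virginia-like bounding box, optionally drawn as Gaussian
blobs around random centers for regional-routing studies. Draws are
vectorized from one seeded generator; no iteration-order-dependent
randomness.

What passing tests on these networks demonstrates: solver exactness,
GA-vs-enumeration optimality at small n, and the *directions* of the
normalization and clustering effects. What they do not demonstrate:
absolute fitness magnitudes, dataset-wide decision percentages, or any
claim about real CMS/VA facilities, whose attribute correlations
(bed count vs cost, rating vs mortality) the independent-uniform
generator deliberately does not model.

## Problem sizes and tolerances

Reference MDPs are 3-state and solve in microseconds; randomized solver
cross-checks use 100 models of 2–5 states. GA-vs-oracle checks use a
7-node tour (720 fixed-start tours enumerated exhaustively) over 100
seeded runs, and enumeration checks for binary problems use length ≤ 10
(1024 chromosomes). Value-iteration tolerance is 1e−12 sup-norm;
cross-solver agreement is required at 1e−6 and Bellman residuals at
1e−9; the linear-scaling round-trip is exact to 1e−12 relative. These
sizes keep the whole suite under a minute on one core while leaving
every check exhaustive or closed-form where an oracle exists.
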