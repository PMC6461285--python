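# Methods

## Model

`emsloc` solves the Maximum Expected Covering Location Problem (MEXCLP) with
two practical modifications: a cap on the number of open bases and dual
urban/rural response-time targets.

Assumptions inherited from MEXCLP: a single system-wide busy fraction `q`,
identical for all ambulances and independent across them; demand is static
(historical incident counts per 1 km grid square); coverage is binary — a
base either reaches a square within its driving budget or it does not.
A point covered by `k` ambulances has expected coverage `1 − q^k`, so the
marginal value of the k-th covering ambulance is `(1−q) q^{k−1}` times the
point's weight — strictly decreasing in `k` for `q ∈ (0,1)`, which is what
produces the urban-backup vs rural-single-coverage trade-off: at low load a
weight-`w` rural point beats the k-th urban backup ambulance as soon as
`w > q^{k−1} W`, and the break-even `k` grows with `q`.

Demand weights are incident counts by default. Population is accepted as an
alternative weight but discouraged: population density and incident density
are imperfectly correlated, and the generator deliberately lets the
per-capita incident rate differ between urban and rural squares so tests
exercise that decoupling.

## Exact solution

The integer program (README shows the full formulation) is assembled sparse
and solved with HiGHS through `scipy.optimize.milp` at a relative MIP gap of
0; a non-optimal solver status raises, never returns silently.

Two formulation choices matter:

* **Coverage-level variables `y_ik` are continuous in `[0,1]`.** Their
  objective coefficients `d_i (1−q) q^{k−1}` are non-negative and
  non-increasing in `k`, and each demand point has a single constraint
  `Σ_k y_ik ≤ Σ_j a_ij x_j`; for any integer `x` the LP optimum in `y` is
  therefore attained by filling `y_i1, y_i2, …` to 1 in order — integral
  without being declared integer. (At `q = 0` the `k ≥ 2` coefficients are
  zero and `y` may come back fractional there, with no effect on the
  objective.) This keeps the MILP's integer part to the `x_j` plus, when a
  base cap is active, the binary `z_j`, and makes the full 180-cell sweep a
  matter of seconds.
* **Base cap via big-M.** `x_j ≤ p·z_j`, `Σ z_j ≤ B` is the standard
  linearization; `p` is the tightest valid M since no base can hold more
  than the whole fleet. The cap constraints are omitted entirely when
  `B ≥ |J|` (vacuous). The three sweep regimes are: candidates restricted
  to the current stations (no cap), all candidates with `B = 5`, and all
  candidates uncapped.

The enumeration oracle (`brute_force_optimum`) evaluates every multiset of
up to `p` ambulances over the candidate set with the plain
`Σ d_i (1 − q^{k_i})` evaluator and is guarded to ≤ 8 bases and `p ≤ 5`
(≤ 1287 multisets of size 5). It shares no code path with the MILP and is
the reference in the solver tests; objective agreement is asserted at 1e−6,
reflecting solver floating-point, not model tolerance.

Optimal allocations are generally not unique. The oracle canonicalizes ties
to the lexicographically smallest `x`; the MILP reports whichever optimum
HiGHS proves, so tests compare objectives, not argmaxes. For the same reason
the "selected base location" report is computed by differencing consecutive
optima and explicitly flags non-nested steps instead of forcing a label.

## Travel times and coverage

Arc driving time is `length / corrected_speed`, in minutes. The speed
correction has three bands — below 40 km/h the posted limit is kept, at
exactly 40 km/h it is multiplied by 1.15, above by 1.20 — plus per-road-name
overrides (defaults: Kirkeveien 1.30, Lågendalsveien 1.40, Riksvei 19 1.40),
all configurable. An override replaces the generic factor, so it applies
only at or above the threshold; below it there is no factor to replace and
the limit is kept. Factors below 1 are rejected.

Demand squares and candidate bases snap to the nearest road **node** by
great-circle distance (ties to the lowest node id). Perpendicular snapping
to edges would be more faithful but the difference is below the 1 km grid
granularity; this is a known limitation for very long edges. Networks are
undirected by default with a per-edge one-way flag; parallel arcs collapse
to the fastest. Shortest paths are Dijkstra (networkx), one pass per base.
Unreachable pairs get `+inf` and are simply never covered.

Coverage uses driving budgets of target − pre-trip delay (defaults
12 − 3 = 9 min urban, 22 min rural) with an **inclusive** comparison:
arriving exactly at the budget counts as compliant, which is the
conventional reading of "within" a target and makes the
budget-monotonicity properties clean.

## Urban/rural classification

A demand point is urban when it belongs to a population center with more
than the cutoff number of inhabitants — strictly greater, so a center of
exactly 10 000 is rural. Cutoff default 10 000; 7000 is the documented
alternative. Official population-center polygons are not derivable from
coordinates, so centers are approximated as connected components of squares
with at least 200 inhabitants/km² under 8-neighbour adjacency (both
configurable); a precomputed `urbanity` column bypasses this entirely, for
users with official designations. Lowering the cutoff can only grow the
urban set — a property test guards this.

## Busy fraction

Hourly busy fractions are estimated from on-duty/busy logs as the
**unweighted mean over records of `busy / on_duty`** per hour-of-day
(configurable to ratio-of-sums). Mean-of-ratios is robust to fleet-size
changes across the logging period; records with `on_duty = 0` carry no
information and are skipped, and hours with no usable record come back NaN
rather than 0. The sweep treats `q` as an exogenous scenario parameter
(0, 0.15, 0.35, 0.5 by default — no load, night, evening, day); the model
does not feed placement back into `q`.

## Synthetic regions

The generator emulates a small mixed urban-rural county on a 1 km grid:
Gaussian-profile population clusters (towns) over a sparse Poisson rural
background, Poisson incident counts with expectation population × per-capita
rate (defaults 0.20 urban, 0.12 rural over the study window), a fully
connected lattice road network with speeds drawn from
{30, 40, 50, 60, 80} km/h so every correction band is exercised, candidate
bases on a 3 km sub-grid, current stations at the largest town centers, and
binomial busy logs around a stated 24-hour profile. Defaults: 24 × 18 km,
three towns of 12–30 thousand inhabitants, rural density 20/km². All
sampling is driven by one `numpy` `default_rng` seed; a deterministic mode
replaces draws by rounded expectations for exact tests.

`deferral_region_params()` fixes the study conditions for the trade-off
analysis: one dominant town (30 000 inhabitants, urban) and one weak remote
settlement (800, rural) with a current base each. The settlements are 40 km
apart so the remote cluster lies outside the other base's 22-minute rural
budget under *every* road-speed draw (22 min at the fastest corrected speed,
80 × 1.20 = 96 km/h, is under 36 km) — isolation is structural, not a
property of one seed. On this region the minimum fleet size that staffs the
remote base rises with the busy fraction (3 → 5 → 6 across
q = 0.15/0.35/0.5 in the shipped configuration).

What the generator does **not** emulate: coastlines and barriers, one-way
streets, time-varying speeds, correlated demand, or the true spatial
statistics of any real region. Tests passing on synthetic regions validate
the pipeline's logic and invariants; they do not calibrate it to any real
road network, and headline coverage percentages from real studies are only
reproducible with the corresponding external road and incident data.

## Problem sizes and runtimes

The default synthetic region yields ~430 eligible demand points and ~50
candidate bases; a full 180-cell sweep solves in well under a minute on one
CPU. Verification suites use 20 random instances within the enumeration
guard and sweeps at fleet sizes 1–10 — sizes chosen so the whole test suite
stays interactive while still covering every regime (all three base modes,
all four busy fractions, capped and uncapped instances).

## Degenerate inputs and edge cases

Zero-population, zero-incident squares are retained but flagged ineligible
(they remain candidate base squares). Empty edge tables give isolated-node
networks; snapping to an empty network, unlabeled demand points, busy counts
exceeding on-duty counts, unknown base types, dangling edge endpoints and
non-positive lengths/speeds all raise validation errors naming the offending
row. `q ≥ 1` is rejected (expected coverage would be degenerate), as are
response-time targets not exceeding the pre-trip delay.
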