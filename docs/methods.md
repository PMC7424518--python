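# Methods

## The model

A spatiotemporal data set is a time-ordered sequence of events
`X = {e_1, …, e_T}`, each event `e_a = (l_a, t_a)` a location plus a
timestamp. Construction of the chronological network proceeds in three
steps: (1) divide the study area into grid cells, each cell a node;
(2) optionally divide time into windows of length `Δt` — one network per
window gives the layers of a temporal network, `Δt` spanning the whole
record gives a single static network; (3) add a directed link from the cell
of `e_a` to the cell of `e_{a+g}` for every sequence lag `1 ≤ g ≤ h`,
accumulating link weights. `w_ij` therefore counts consecutive
co-occurrences of events in cells *i* and *j*; `i = j` is a self-loop
counting runs of activity inside one cell. An optional distance cutoff
`d_max` (Euclidean for planar coordinates, haversine kilometres for
longitude/latitude) suppresses links between far-apart events.

Assumptions worth making explicit:

* **Time is an order, not a scale.** Only the ordering (and, for `Δt` and
  parallel grouping, equality) of timestamps matters to the link rule.
  Timestamps are normalised to integer keys (epoch seconds for dates).
* **Parallel events.** Events sharing a timestamp are grouped; every node
  with an event at one timestamp links to every *different* node with an
  event at the next one (all combinations of different nodes between the two
  groups, one weight unit per node pair). When both groups are singletons
  this is the plain consecutive-pair rule, which *does* allow `i = j`; a
  flag (`parallel_self_loops`) extends self-loop counting to genuine
  parallel groups.
* **Window semantics.** "Within a window of size `h`" is read as all lags
  `1 … h`; `strict_lag` restricts to exactly `h`. At `h = 1` — the default
  used by every analysis here — the two readings coincide.
* **Undirected analysis.** All default analyses aggregate to the undirected
  graph, `w^u_ij = w_ij + w_ji` (total co-occurrences regardless of order);
  self-loop weights carry over unchanged.

Exact identities used as test oracles: with distinct timestamps, self-loops
on and no distance cutoff, `Σ_ij w_ij = Σ_{g=1..h} max(0, T − g)`; an
independent O(T·h) pair enumeration reproduces the weighted edge multiset;
pruning thresholds nest, `τ' ≥ τ ⇒ E(τ') ⊆ E(τ)`.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `h` | sliding window (event steps) | 1 | consecutive pairs; the only case the downstream analyses need |
| `d_max` | max event-pair distance | off | most grids already localise; enable for noisy geolocation |
| `Δt` | snapshot length (time units) | off | off = single static network |
| `τ` | pruning threshold (weight) | 0 | `w ≤ τ` links removed; small values already delete many weak links because most nodes have low strength — pick per data set |
| `δ` | label-correction radius (events, odd) | 1–5 | see "Smoothing" below |
| grid size | cells per axis | user decision | no a-priori rule: finer grids are sparser and larger, coarser grids lose spatial detail; the package never guesses silently (only `fit_bounds` + explicit `nx, ny`) |

## Measures

Degree counts distinct neighbours, excluding self-loops. Strength is the
row sum `s_i = Σ_j w_ij`, which includes the `j = i` term, so self-loops are
included by default (flag to exclude); with all weights ≥ 1 and self-loops
excluded from both, `s_i ≥ k_i`. Path statistics are hop counts by default
(a path length is a count of consecutive-event steps) and are computed on
the largest connected component, with a coverage report, since pruning can
disconnect the graph. Weighted closeness maps weight to distance as `1/w`:
strong links are short temporal distances. Betweenness is the unnormalised
pair count `Σ_{j<k} n_i^{jk}/g^{jk}`. Transitivity is the global clustering
coefficient on the self-loop-free graph.

Tail fitting: the discrete power-law exponent is estimated by maximum
likelihood with the lower cutoff chosen by Kolmogorov–Smirnov minimisation
(Clauset-style, via igraph's plfit); the log-normal by MLE on log-values,
with a truncation-corrected variant used when comparing both families above
the same cutoff. The comparison reports both KS distances and deliberately
stops short of declaring a sample scale-free — with exponents well above 3
the hubs are rarer than a scale-free label would suggest.

## Communities, clustering, change points

Community detection runs on the undirected weighted graph with self-loops
dropped. The agglomerative method (fast greedy modularity) returns the
best-modularity cut plus the full dendrogram, so any number of communities
`k` can be requested afterwards; community ids are relabelled contiguously
from 1 ordered by smallest member node, making partitions deterministic.
Label propagation is order-dependent, so it is seeded and restarted
(default 10 restarts) and the maximal-modularity run is reported.

Event clustering assigns each event the community of its cell, giving the
label sequence `C`; change points are the 1-based indices `t ≥ 2` with
`c_t ≠ c_{t−1}`.

### Smoothing

The correction `f(C, δ)` replaces `c_t` by the surrounding value when the
window `{c_{t−δ}, …, c_{t−1}, c_{t+1}, …, c_{t+δ}}` — read off the
*original* sequence, excluding `c_t` — contains exactly one unique value.
All corrections apply simultaneously, so the result is scan-order
independent; boundary positions without a full window are left unchanged
(the rule is undefined there; leaving them is the conservative choice). Two
consequences follow from reading the rule literally. First, it can rewrite
non-outlier positions: in `[1,2,1,2,1]` with `δ = 1` every interior window
is uniform and the result is `[1,1,2,1,1]`. Second, the radius trades
correction power against interference: an isolated wrong label is corrected
at any `δ`, but two wrong labels within `δ` of each other block each
other's windows and both survive. Since the generators plant outliers as
isolated single events, `δ = 1` maximises corrections there and is used in
the four-period reproduction; larger radii (5 in the Gaussian-burst checks)
behave identically when wrong labels are rare and well separated.

## The synthetic generator

`generate_from_matrix` emits, at each step `t = 1 … T`, one event per cell
with per-cell probability `P_ij` (position uniform inside the cell, all
events of a step sharing the timestamp). It emulates a spatially
inhomogeneous, temporally independent event process — the spatial emission
pattern is the ground truth the chronnet is supposed to recover. It does
*not* emulate spatial correlation between neighbouring cells, temporal
autocorrelation, drifting rates, or measurement noise in coordinates, all
present in real detection products; passing tests therefore show that the
pipeline recovers planted structure under ideal sampling, not that any real
data set will be as clean.

Scenario defaults and the reasoning behind them:

* **Four-period scenario** — 20×20 grid, `T = 12,000` split into four equal
  intervals, the active quadrant's cells emitting at `p_in = 0.02` per step
  and all other cells at `p_out = 10⁻⁵` (≈ 9 outlier events per period).
  The in-region probabilities are arbitrary by design; these values give
  ≈ 6,000 events per period with outliers sparse enough to be isolated in
  the event sequence.
* **Alternating Gaussians** — bursts of isotropic Gaussian points
  (`σ = 100`) cycling among fixed centers on a `[0, 3000]²` domain, gridded
  10×10. The domain size is chosen so the clusters are genuinely separated:
  every center lies ≥ 7.5σ from the nearest community boundary, so
  essentially no event falls into a cell dominated by another cluster. (On a
  1000-unit domain the boundary sits at 2.5σ and ~0.6 % of events cross it;
  pairs of such events within one smoothing window survive correction and
  produce spurious change points — the separated geometry is what the
  scenario is meant to model.) Full-scale runs use 40 bursts × 25,000
  events; the test suite uses 40 × 2,500 to keep runtimes in seconds, which
  does not change the structure, only the link-weight scale.
* **Chaotic trajectories** — Lorenz (`σ = 10, β = 8/3, ρ = 28`, step 0.01,
  duration 200, projection x–y) and Rössler (`a = b = 0.2, c = 5.7`, step
  0.02, duration 1000, projection x–z), integrated with classic fixed-step
  RK4 from initial conditions `(1,1,1)` / `(1,1,0)` with 10 time units of
  transient discarded; an optional seed jitters the initial condition by
  ±0.5 per coordinate. The attractor geometry is insensitive to these
  choices; network-level features that depend on the exact realisation
  (e.g. which single cell bridges the two Lorenz lobes after pruning) are
  documented but not asserted.

## Numerical choices and degenerate inputs

* Cell assignment uses half-open cells `[low, high)` with the last cell per
  axis closed, so the maximum coordinate is assignable; the convention is
  total and matches the floor formula exactly (oracle-tested).
* Grids with zero extent along an axis are rejected rather than patched — a
  silent epsilon would move cell boundaries invisibly.
* `fit_discrete_powerlaw` requires at least two distinct positive values;
  `fit_lognormal` at least two distinct positives. Degenerate samples raise.
* Outlier selection takes `ceil(fraction · n)` nodes, at least one, with
  ties broken by node id, so results are deterministic.
* Label-propagation seeding drives igraph's RNG through Python's `random`
  module; each restart draws its own sub-seed from a seeded generator.
* The MCD14ML confidence filter is strictly `> min_confidence` (default
  75), and parsing failures are collected into a line-numbered report
  instead of being silently dropped or aborting the run.

## Problem sizes used by the checks

The reproduction checks run the four-period scenario at full scale
(`T = 12,000`, 10 seeds), the Gaussian scenarios at 40 × 2,500 events
(10 seeds each for 2 and 3 centers), the emission-family contrasts on a
10×10 grid at `T = 5,000` (5 seeds), brute-force construction equivalence at
`T = 200`, exhaustive path/centrality oracles at n ≤ 30 nodes, and estimator
recovery at n = 10⁴ samples.

## Known limitations

* Construction is single-process; `merge` supports chunk-parallel builds but
  the chunking itself is left to the caller.
* Geographic hexagonal gridding is analytic only (cell counts and mean
  areas of aperture-`a` icosahedral grids, `10·a^r + 2` cells at resolution
  `r`); per-event hexagon assignment must come from an external DGGS tool
  via `load_cell_assignment`.
* Temporal-network analytics beyond snapshot construction (inter-layer
  measures, temporal paths) are out of scope.
* The ST-DBSCAN baseline is not reimplemented; `adjusted_rand_index` scores
  any externally produced labelling against the chronnet clustering.
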