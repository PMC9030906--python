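# Methods

## Network construction

Input is a complete daily AQI panel (date × site) and a site table with
WGS-84 coordinates. For sites i, j the Pearson coefficient `r_ij` is computed
over the full common date range. The edge threshold defaults to the
arithmetic mean of the `n(n−1)` off-diagonal correlation entries; this
data-driven rule keeps the size of the largest connected component stable
across panels, whereas a fixed threshold behaves very differently on panels
with different baseline correlation. The comparison is `r_ij >= threshold` by
default (`>` is available), and the threshold can be overridden with a fixed
value. A configured threshold that admits a non-positive correlation is a
hard error: edge weights must be positive.

Distances are geodesic kilometres on the WGS-84 ellipsoid, computed with
Vincenty's inverse formula (implemented in `aqinet.geodesy`; the rare
near-antipodal non-convergent pairs fall back to the spherical haversine
value with a warning — irrelevant at regional scale, where the two models
agree to well under a percent). Each pair's **distance coefficient** is
`c_ij = d_ij / max(d) ∈ (0, 1]`. Two distinct sites with identical
coordinates are rejected, since a zero distance would make the weight
unbounded.

Edge weights: pre-rescaling `w'_ij = r_ij / c_ij` on surviving edges only,
then `w_ij = w'_ij / max(w')` so the strongest surviving edge has weight
exactly 1. The rescaling maximum is taken over edges that passed the
threshold, not over all pairs — only edges carry weights. Isolated nodes
(no correlation reaches the threshold) stay in the node universe, flagged
excluded; they are reported, carry zero influence, and are omitted from
path-based statistics.

## Topology statistics

On a network with `n` nodes, `m` edges and `c` connected components among
the `n_a` active (non-isolated) nodes:

* **Density** `Gd = m / (n(n−1)/2)`. The node basis defaults to *all* nodes
  (isolated ones included) and can be switched to active nodes. The default
  mirrors how a station network with one excluded station is summarised:
  the isolated station still counts in the denominator.
* **Efficiency** `Ge = 1 − V / max(V)` where `V = m − (n_a − c)` is the
  number of edges beyond a spanning forest and
  `max(V) = Σ_components (n_k−1)(n_k−2)/2` is the redundancy of the complete
  graph on each component. `Ge` is defined as 1 when `max(V) = 0` (forests).
  Efficiency is always computed on active nodes. Low efficiency = many
  redundant connections = a robustly coupled network.
* **Rank degree** `Gr = 1 − S / max(S)` with `S` the number of unordered
  pairs that are *symmetrically* reachable and `max(S) = n_a(n_a−1)/2`. On an
  undirected graph reachability is symmetric, so `Gr` equals the fraction of
  disconnected pairs and is exactly 0 for any connected undirected network;
  the statistic only measures hierarchy on directed reachability, and a
  directed graph may be passed to get that variant. Reported `Gr` values
  near 0.9 for connected undirected networks in the source literature cannot
  be reproduced under this definition; the orientation behind them is
  unknown, and they are deliberately not targets of this package's checks.

Recomputed efficiencies for the two published city networks (0.530 and 0.464
from the printed n, m) differ in the third decimal from the printed 0.531
and 0.476; the source of that discrepancy is unknown and those two values
are likewise not treated as targets. The station-network value (0.156 from
n = 11, m = 48) reproduces exactly.

## W_LGI influence score

For node `v_i`: `dw(v_i) = Σ_j w_ij` (weighted degree),
`W_LI = dw/n`, `W_GI = Σ_{j≠i} dw(v_j)/(d_ij + θ)`,
`W_LGI = W_LI × W_GI`, ranked descending with deterministic tie-breaking
(descending `dw`, then canonical site order). Excluded nodes score 0 and
rank last. Unreachable pairs contribute nothing to `W_GI` (equivalent to
`d_ij = ∞`), which keeps the score finite on disconnected networks.

Parameter choices, with rationale:

* **`n` in `W_LI`** — the active node count of the analysed network
  (configurable to all nodes). Published score tables are consistent only
  with the active count.
* **`θ` (damping, default 0)** — no principled nonzero value presents
  itself, and `θ = 0` has a clean property: rescaling all edge weights by
  `c` rescales both `dw` and the weight-sum distances by `c`, so `W_GI` is
  scale-free, `W_LGI` scales by `c`, and the *ranking* is invariant.
* **Path length (default `weight_sum`)** — the shortest distance between two
  nodes is the minimum over paths of the *sum of edge weights*, as the score
  was defined. Note the inversion this implies: a heavy (strongly coupled)
  edge counts as a *long* step, so `W_GI` systematically favours nodes whose
  incident edges are light — a node's distances are bounded below by its
  lightest incident edge. In the published city networks `W_GI` varies by
  only a few percent across nodes and `dw` drives the ranking, so the
  inversion is inconsequential there, but it is a real property of the
  definition. An `inverse_weight_sum` mode (edge length `1/w`) is provided
  for users who want "strongly coupled = close".

## Synthetic panels

`aqinet.synth_data` generates the test bed:

    X_i(t) = mean_level + seasonal_amplitude · sin(2πt/365)
             + λ_i · F(t) + ε_i(t)

with `F` a stationary AR(1) latent regional factor (unit innovation
variance, persistence φ) and `ε(t) ~ N(0, σ² exp(−d_ij/ρ))` — the simplest
kernel expressing "closer sites co-vary more". Values are truncated at 0
(AQI is nonnegative); an optional `missing_rate` blanks random cells to
exercise the imputation path.

Defaults — 13 sites, 365 days, baseline 80, seasonal amplitude 30, loadings
15, φ = 0.7, σ = 20, ρ = 300 km, a ~5°×5° mid-latitude box — were chosen to
put the mean off-diagonal correlation near 0.75–0.85, the regime reported
for real one-year agglomeration panels. What the generator does *not*
emulate: wind-driven advection (correlation here is isotropic in distance),
heavy-tailed pollution episodes (noise is Gaussian), and weekly emission
cycles. Passing tests therefore demonstrate correctness of the pipeline
and of the score algebra under realistic correlation structure, not
meteorological fidelity.

### The planted-hub rank-recovery experiment

`plant_hub` relocates one site to the geometric centre of the others and
doubles its factor loading, making it by construction the most strongly and
most centrally coupled node; the experiment asks how often the W_LGI
ranking puts it first across independent panels. This premise requires a
controlled design, codified in `hub_recovery_config()`:

* **grid layout** — with uniform random placement, an accidental
  near-coincident pair receives the maximal edge weight (the weight
  rescaling is driven by the closest pair) and its endpoints can dominate
  the ranking for purely geometric reasons, so the planted node is not the
  ground-truth answer the experiment assumes;
* **no seasonal term** — a deterministic cycle shared by every site inflates
  all pairwise correlations equally and compresses the contrast created by
  the planted loading; observational correlation studies remove exactly
  this component by deseasonalising first.

Factor and noise parameters stay at the generator defaults. A degenerate
fully deterministic panel (σ = 0) does **not** guarantee hub rank 1: all
correlations collapse to ≈1, weights reduce to inverse distance, and the
weight-sum path inversion described above can flip the product against the
heaviest node — the stochastic experiment, not the degenerate limit, is the
meaningful check.

## Numerical and edge-case choices

* Pearson via `numpy.corrcoef`, symmetrised and clipped to [−1, 1]; a
  zero-variance site is a hard error naming the site. At least 3 dates
  are required.
* Daily aggregation: arithmetic mean of available hours; days with fewer
  than `min_hours` observations (default 1) become missing.
* Imputation: time-based linear interpolation, which degenerates to the
  mean of the two neighbours for a single-day gap; series ends take the
  nearest observed value; the count of filled cells is reported. A site
  with no observations at all is a hard error.
* Timestamps are taken as local civil time; no timezone conversion.
* Shortest paths via Dijkstra (`networkx`), valid because all edge lengths
  are positive in both path modes.
* Problem sizes in the test suite (panels up to 26 sites × 365 days,
  Monte-Carlo loops of 50 panels, oracle sweeps over hundreds of ≤ 8-node
  graphs) were chosen so the whole suite runs in a few seconds while still
  exercising every code path at the scale of the motivating application.

## Known limitations

* Contemporaneous correlation only: no lags, no directionality, no
  causal claims — an edge is co-variation, not transport.
* One representative coordinate per site; no areal geometry.
* The mean-threshold rule has no significance interpretation; users wanting
  inference should threshold on p-values instead (out of scope here).
* The weight-sum path semantics of `W_GI` (see above) is kept for fidelity
  to the score's definition; rankings in sparse or weight-heterogeneous
  networks can be sensitive to the `path_length_mode` choice.
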