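# Methods

## The model

`gwsn` simulates the formation of a weighted, undirected social network
among `N` agents. Each agent `i` carries two kinds of fixed attributes,
drawn once at initialization and immutable thereafter:

* a position `(x_i, y_i)`, uniform on the unit square with periodic
  boundary conditions (a torus), giving a geography through the
  minimum-image Euclidean distance `r_ij`;
* a feature vector `σ_i = (σ_i^1, …, σ_i^F)` with each trait `σ_i^f`
  uniform on `{1, …, q}`, giving a homophily structure: for any single
  interaction a feature `f` is drawn uniformly and only pairs with
  `σ_i^f = σ_j^f` may interact.

Link weights `w_ij ≥ 0` encode tie strength; `w_ij = 0` means the link
is absent. The network starts empty.

Each Monte Carlo step visits every node once, in a freshly shuffled
order; a visited node performs one **global attachment** (GA) and one
**local attachment** (LA) event. After all node updates, three
termination sweeps run over the whole network, in the order node
deletion → link deletion → aging.

**Global attachment (focal closure).** Node `i` draws a feature `f` and
forms the candidate set `Γ_i^f` of same-trait non-neighbors. A partner
`j ∈ Γ_i^f` is selected with probability proportional to `r_ij^(-α)`;
`α = 0` removes the geographic constraint entirely. If `i` is isolated
the link is created unconditionally, otherwise with probability `p_r`.
New links start at weight `w0`.

**Local attachment (triadic closure).** Node `i` draws a feature `f`
and walks two hops: first to a same-trait neighbor `j` with probability
`w_ij / Σ w`, then from `j` to one of its other same-trait neighbors
`l ≠ i` with probability `w_jl / Σ w`. If `i` and `l` are not yet
connected, the triangle closes with probability `p_delta` and the new
link starts at exactly `w0`. Whether or not a new link is created, the
traversed links `i–j` and `j–l` are reinforced by `+w_r`, and a
*pre-existing* `i–l` link is reinforced as well. If either candidate
set of the walk is empty the whole event is a no-op — no partial
reinforcement. (The reinforcement scope — traversed links always, a
pre-existing closing link too, a freshly created one not — follows the
convention of the earlier weighted-social-network models this model
generalizes; the definition leaves the point open.)

**Termination.** Each node, with probability `p_nd`, is replaced by an
isolated node: all incident links are removed while its position and
traits are kept (resampling them is not part of the mechanism). Each
link is deleted independently with probability `p_ld`. Finally every
surviving weight is multiplied by `1 − A` and links falling below the
threshold `w_th` are removed, so immediately after the aging sweep
every extant weight is at least `w_th`.

`w0 = 1` and `w_th = 0.5` are fixed throughout — they only set the
weight scale. The sampled input box for the remaining ten parameters is

| parameter | range | scale |
|---|---|---|
| `N` | [2000, 5000] | integer |
| `F` | [1, 10] | integer |
| `q` | [1, 10] | integer |
| `alpha` | [0, 4] | linear |
| `p_r` | [1e-5, 1e-2] | log10 |
| `p_delta` | [1e-3, 1e-1] | log10 |
| `w_r` | [0, 2] | linear |
| `p_nd` | [1e-5, 1e-2] | log10 |
| `p_ld` | [1e-6, 1e-3] | log10 |
| `A` | [1e-5, 1e-1] | log10 |

Useful reductions, exercised by the tests: `q = 1` disables homophily
(every pair may interact); `p_nd = p_ld = A = 0` disables termination,
and the network then grows monotonically toward the complete graph;
`A = 0, w_r = 0` freezes all weights at `w0`.

## Simulation protocol

A run iterates to `t_max` (default 50,000) and measures the nine
network statistics every `measure_every` steps (default 5,000), so a
default run yields 10 checkpoints. If the average degree exceeds
`k_th = 150` at a checkpoint the run is aborted: the network is no
longer sparse at the sampled sizes and the densification regime is both
expensive and uninformative. The triggering checkpoint is not recorded;
earlier checkpoints are kept and flagged.

One integer seed drives a whole run. Population initialization consumes
a NumPy `Generator` stream first; a seed derived from that stream then
initializes the JIT kernel RNG that drives the per-step dynamics, and
the Python-level stream continues to supply the percolation
tie-shuffles at checkpoints. Runs are bit-reproducible given the seed.

### Implementation notes

The per-step loop is JIT-compiled (numba) over flat adjacency arrays
with capacity doubling. Two observational equivalences keep the
asymptotic cost near `O(N + L)` per step:

* the GA creation coin (`p_r`, when `k_i > 0`) is drawn *before* the
  partner selection — selection has no side effects, so skipping the
  candidate scan when the coin fails changes nothing observable;
* for `α = 0` the uniform GA partner is drawn by rejection sampling
  from the trait bucket (falling back to explicit enumeration after 30
  misses, which preserves uniformity exactly); for `α > 0` the kernel
  matrix `r^(-α)` is precomputed once per run.

Coincident positions (`r_ij = 0`, probability zero under continuous
sampling) are floored at `r = 1e-12` to keep the kernel finite.

## Network statistics

For one snapshot the suite reports: average degree `⟨k⟩ = 2L/N`; degree
assortativity `ρ_k` (Newman's excess-degree correlation over link
ends); average link weight `⟨w⟩` over the `L` positive-weight links;
average local clustering `C` (unweighted; `c_i = 0` for `k_i < 2`,
included in the mean); average link overlap `O` with
`o_ij = n_ij / ((k_i − 1) + (k_j − 1) − n_ij)` and `o_ij = 0` when the
denominator vanishes (an isolated dyad has no possible common
neighbor); the Pearson correlations `ρ_ck` (clustering vs degree, over
nodes) and `ρ_ow` (overlap vs weight, over links); and the two
weight-ordered link-percolation transition points, reported rescaled as
`(1 − f_c)⟨k⟩` — the average number of neighbors per node remaining at
the transition.

Undefined statistics (empty network, zero variance, fewer than two
links) are NaN, never a silent zero; campaign CSVs write them as empty
cells.

**Percolation.** Links are removed one by one in weight order
(ascending = weakest first). Since no disintegration criterion is
canonical, the transition is located by the standard susceptibility
peak: `χ(f) = Σ' s² n_s / N` over component sizes excluding the largest
component, maximized over `f ∈ {0, 1/L, …, 1}`; ties in `χ` are broken
toward smaller `f`. The sweep is implemented as reverse-order link
addition with union-find, `O(L α(N))`. Equal weights are tie-broken by
a seeded shuffle so that the ordering among indistinguishable links is
unbiased; on fixtures with unique weights the result is independent of
the shuffle seed. A largest-single-drop-of-the-giant detector is
available behind `detector="giant_drop"`. On random graphs with
uniformly random weights the estimator is calibrated by the classical
Erdős–Rényi threshold: the transition occurs when about one neighbor
per node remains, `(1 − f_c)⟨k⟩ ≈ 1` (finite-size effects bias the
susceptibility peak slightly above 1 at `N = 1000`).

A large gap between the ascending and descending transition points
(`f_c^a ≪ f_c^d`) diagnoses Granovetterian organization: strongly tied
communities bridged by weak links. In the strong-reinforcement regime
(`w_r ≈ 1`, node-deletion-only turnover) the simulator reproduces this
signature together with `ρ_ow > 0`.

## Campaigns and the training table

A campaign samples parameter sets i.i.d. uniformly on each parameter's
scale, runs `n_seeds` independent simulations per set (5 in the
standard protocol), and emits one table row per (set, seed,
checkpoint): 11 input features (10 parameters + `t`), the nine
statistics, the per-run seed and the abort flag. Per-run seeds are
derived counter-style via `SeedSequence(master_seed, spawn_key=(set,
seed_index))`, so campaigns are reproducible as a whole while runs are
independent, and optional process-level parallelism cannot change
results. Rows recorded before an abort are retained and flagged rather
than discarded — they are valid measurements of the pre-abort
trajectory.

## Metamodels

Each output property gets its own surrogate: a multilayer perceptron
with three hidden layers of 30 ReLU units and a linear output, trained
to minimize MSE with Adam (batch 200, 2,000 epochs, learning rate
0.001; a grid-search helper covers the 0.001–0.01 range). The
implementation is scikit-learn's `MLPRegressor` with early stopping
disabled so the epoch budget is honored.

Inputs are scaled to `[0, 1]`: log10 axis for the log-sampled
parameters, linear for the rest; `t` is scaled linearly over the
checkpoint range `[measure_every, t_max]` (it is not a log-sampled
quantity). The average link weight spans orders of magnitude, so its
surrogate regresses `log10⟨w⟩`; all other targets are untransformed.
Rows whose target is undefined are dropped per-target, not imputed.

Train/validation/test splits are 80/10/10 **by parameter set**, never
by row — the five seeds and ten checkpoints of one parameter set are
highly correlated, and a row-level split would leak them across the
split. Evaluation reports the test MSE on the transformed target scale
next to the test-target variance; an informative surrogate has
MSE ≪ variance (a mean predictor has MSE = variance exactly).

Persistence uses a joblib archive holding the per-target regressors,
the scaler and the config; a round-trip must reproduce predictions
exactly.

## Sensitivity analysis

First-order and total-effect Sobol indices of each surrogate are
estimated with the Saltelli design (base matrices A, B plus the d
radial matrices, `n_base·(d + 2)` evaluations) and the Jansen
estimators

    S_i  = (V − ½·mean((f(B) − f(AB_i))²)) / V
    S_Ti = ½·mean((f(A) − f(AB_i))²) / V

with percentile-bootstrap 95% confidence intervals over the base rows.
The estimator forms are fixed here, rather than delegated to a
sensitivity package, so results are reproducible independently of any
library version. Input distributions mirror the training design
(uniform per scale; `t` uniform over the checkpoint range); integer
parameters are treated as continuous because the surrogate is defined
on the continuous box. Small negative index estimates are sampling
noise: they are reported as-is with a flag, never clipped. A zero-
variance output marks all its indices undefined. A nested-quadrature
brute-force transcription of the first-order definition (d ≤ 3) serves
as an independent oracle in the tests, validated against the analytic
Ishigami decomposition.

## Scaled-down study sizes

The desk-scale defaults used by the test suite and the acceptance
script are deliberate choices that keep every analysis on one CPU while
preserving the qualitative regimes: populations of 200–2,000 nodes,
horizons of 2,500–50,000 steps, campaigns of 60–200 parameter sets with
2 seeds each, surrogate training tables of order 10³–10⁴ rows. At these
sizes the surrogate's absolute MSE is far from what a campaign of
hundreds of thousands of parameter sets would achieve; the pipeline
checks are therefore structural (MSE below target variance, correct
response direction, recovery of planted dependencies and closed forms)
rather than comparisons against any particular large-campaign MSE.

## Known limitations

* The synthetic nature of the model is the point — but note that
  passing tests validate the simulator against its own definition and
  against closed forms, not against empirical social networks.
* The susceptibility-peak transition detector is one defensible choice;
  near-critical finite-size effects bias `f_c` slightly, visible in the
  Erdős–Rényi calibration.
* Surrogates are only defined inside the sampled box; predictions at
  out-of-range inputs are refused rather than extrapolated.
* The abort rule is evaluated at checkpoints only, so a run may
  overshoot `k_th` between checkpoints; mid-epoch degree tracking would
  cost more than it informs.
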