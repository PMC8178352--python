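# Methods

## Model

We model `n` islands (demes) of equal relative size `s` exchanging
migrants symmetrically, with `M` the total migration rate received by one
island per unit of `2N` generations.  A history is *piecewise stationary*:
`γ ≥ 0` event times `t_1 < … < t_γ` split time into `c = γ + 1`
components, each with its own `(M_i, s_i)`; the number of islands never
changes (no splits, joins or extinctions).  Throughout the package deme
sizes default to 1 and the search fixes them by degenerate bounds, leaving
`2γ + 2` free parameters (`+1` for the reference size `N` in scaled fits).

For a sample of two lineages drawn from one deme (the PSMC sampling
scheme: one diploid individual) exchangeability of demes lumps the
structured coalescent into three states — same deme `S`, different demes
`D`, coalesced `C` — with per-component rates `S→C: 1/s`, `S→D: M`,
`D→S: M/(n−1)`.  The survival and density of the coalescence time follow
from propagating the initial distribution `(1, 0)` on `(S, D)` through
consecutive components with matrix exponentials of the 2×2 transient
block; the density is computed directly as (mass on S)/s, never by
numerical differentiation.  The IICR is their ratio.

Numerics: the 2×2 transient block provably has real, distinct, negative
eigenvalues (its off-diagonal product is `M²/(n−1) > 0` and its trace and
determinant are negative and positive respectively), so the matrix
exponential is evaluated in closed spectral form.  This makes the engine
vectorizable over both evaluation times and whole candidate populations —
the optimizer evaluates an entire differential-evolution generation in a
handful of numpy operations — and is cross-checked in the test suite
against `scipy.linalg.expm` and against an independent
`numpy.linalg.eig` two-exponential solution of the stationary model
(sup-error < 1e-10 over a lattice of `(n, M)` values).

Scaling: the dimensionless curve (time in `2N` generations, values
relative) is mapped to PSMC units by `sIICR(g) = N · IICR(g / 2N)`.  In
scaled fits the event-time coordinates and bounds are expressed in
generations and converted through the candidate's own `N`.

## Targets

Three target types are supported.

* **Exact**: the engine's own curve discretized on a log grid — the
  right-endpoint value `y_j = P(T2 > τ_j)/f(τ_j)` on each interval.
  Default grid: 64 log-spaced points (mirroring PSMC's atomic-interval
  resolution) on `[1e-2, 2e2]` in `2N` generations.  The upper edge
  deliberately exceeds the largest admissible event time (100) so that no
  admissible component is invisible to the objective; an event allowed to
  sit at the last grid node would be unidentifiable.
* **T-sim**: `T2` draws from a Gillespie walk on the lumped chain
  (holding times exponential per state, jumps per the embedded chain,
  component boundaries handled by truncation), turned into an empirical
  curve via the Kaplan–Meier survival function (lifelines; with no
  censoring this is the empirical survival).  Each bin inverts the
  stepwise survival representation exactly, `y_j = Δτ_j / ln(S_{j-1}/S_j)`,
  which is unbiased wherever the IICR is constant across the bin; the
  first-order ratio `S Δτ / (S_{j-1} − S_j)` overshoots by up to ~150% on
  wide log-spaced tail bins and is kept only as the fallback for a
  terminal bin whose empirical survival reaches zero.  Empty bins donate
  their span to the next emitted interval; trailing empty bins are
  dropped.
* **PSMC**: the Li & Durbin text format.  The parser keeps the final RD
  block (the converged EM iteration); `N0 = θ0 / (4 μ s)` with bin size
  `s` (default 100), times scale by `2 N0`, values by `N0`.

## Objective

The density-weighted distance is

```
d_ω = Σ_j |y_j − IICR_φ(τ_j)| · w(τ_{j−1}) · (τ_j − τ_{j−1}),
w(τ) ∝ f0(τ)^ω,   Σ w = 1 (plain sum over the left endpoints used),
```

where `f0` is reconstructed from the target itself:
`f0(τ_j) = exp(Σ_{k≤j} (τ_{k−1} − τ_k)/y_k) / y_{j+1}` — survival implied
by the step curve divided by the (right-continuous) step value at the
node.  `ω = 1` by default; `ω < 1` dampens the density weight and moves
emphasis toward ancient epochs.  A `time_range` option restricts the sum
to intervals fully contained in a window (weights renormalized over the
kept intervals, so `ω` keeps its meaning on the window); this is how a
suspect recent expansion or untrustworthy ancient tail is excluded when
fitting real PSMC curves.  The visual distance (plain sum of node
differences, natural on a log-time plot) is available as an alternative.

Candidate evaluation uses the exact engine at the target's grid nodes
(right endpoints).  Propagation under- or overflow maps to a large finite
penalty so the optimizer survives pathological corners of the box.

## Search

Parameters are encoded for a box-constrained continuous optimizer: `n` as
a continuous coordinate rounded on decode, event times in log10 (sorted on
decode, making the objective symmetric under coordinate permutation — no
ordering penalty needed), migration rates linear, `N` in log10.  The
search runs scipy's differential evolution in *rounds*: one round is a
full DE convergence cycle (population `15 ×` dimension, mutation dithered
on `[0.5, 1)`, recombination 0.7, per-round relative tolerance 0.01,
generation cap 300, vectorized objective) whose initial population is
uniform random except that from the second round on one member carries the
best vector found so far.  Each round's result is sharpened by a
Nelder–Mead simplex polish (the gradient-based polish inside scipy's DE
cannot extract the final digits of an L1 objective).

The dominant failure mode at `c ≥ 3` is **component misassignment**: the
search parks two event times on top of each other (a zero-width component
with an arbitrary rate — observationally equivalent to dropping one
event) and misses a genuine but weakly expressed event elsewhere.  Such
solutions are strong local optima; no reasonable budget of random
restarts escapes them because the true basin can be a few percent wide in
every coordinate.  A repair move therefore deletes each event in turn and
re-inserts an event on a coarse lattice of (time, rate) proposals
spanning the bounds, also trying neighboring island counts.  All
proposals are scored in one vectorized call; within each structural
family (which event was dropped, which side of the split keeps the old
rate, which island count) and each band of insertion times, the best
proposal that is genuinely distinct from the incumbent is refined in the
two inserted coordinates, the best refinements get a full simplex polish,
and — if nothing improved — the best alternative structure is repaired
once more recursively (two simultaneously misplaced events).  A result is
accepted only if it beats the incumbent.  The repair runs whenever the
incumbent has improved meaningfully since the last repair; after the
round budget a single heavier pass (wider island-count span, finer
insertion bands, more polished candidates) runs on the final incumbent.

Some components are genuinely unidentified: a short component, or a
rate change of a fraction of a percent, can leave no numerical trace on
the curve, so histories with wildly different rates for that component
all fit below the convergence tolerance (observed ties at 1e-15 relative
curve difference).  Among such observationally equivalent optima the
search canonically returns the least-changing connectivity — the fit
minimizing the total absolute log rate ratio between consecutive
components, adopted only when it still fits below the tolerance.  This
also keeps inferred connectivity graphs free of arbitrary rate spikes in
zero-width components.  On batches of three- and four-component scenarios this
converts most misassigned fits into machine-precision recoveries, and
most scenarios then converge in one to five rounds.

The loop stops when the distance falls below `ε` (default `1e-10`
dimensionless, `1e-7` scaled — meaningful only for exact targets, where
zero distance is attainable) after at least `min_rounds`, or at
`max_rounds`.  The per-round best distance is nonincreasing by
construction.

## Validation loop and scoring

Scenario sampling is either *continuous* — `n` discrete-uniform, `t_i`
log-uniform base 10 (sorted after the joint draw), `M_i` and `s_i`
uniform, one spawned RNG stream per scenario so batches are reproducible
and extendable — or *discrete*: tuples drawn uniformly without
replacement from the Cartesian product of finite value sets
(`n ∈ {2,5,10,15,20}`, `t ∈ {0.1,0.5,1,2,5,10,20,50}`,
`M ∈ {0.1,0.2,0.5,1,2,5,10,20,50}`, `s = 1`), rejecting tuples with equal
migration rates in consecutive components or tied event times (a
zero-width component is undefined).

Inference always runs in bounds strictly wider than the sampling space:
sampling uses the hull of the discrete sets (`n ∈ [2,20]`,
`t ∈ [0.1,50]`, `M ∈ [0.1,50]`), inference uses `n ∈ [2,50]`,
`t ∈ [0.05,100]`, `M ∈ [0.05,100]`.

Recovery is scored per parameter by the normalized RMS deviation
(nRMSD): RMS(inferred − true) divided by the range of the true values
(falling back to their common magnitude when all true values coincide,
which keeps one-component batches well defined).  Because the log-uniform
time prior spans orders of magnitude and makes time nRMSDs
outlier-dominated, a secondary `log10(t)` nRMSD column is also reported.
Band fractions count scenarios within 10% relative error (50% for event
times).  Misassignment diagnostics greedily match inferred to true event
times in log-time and flag an inferred rate that is closer (relative
error) to a neighboring component's true rate than to its own; the
diagnostic never alters inference output.

## Problem sizes

The shipped acceptance runs use desk-scale batches chosen so the whole
report recomputes in well under half an hour on one core: `L = 15`
scenarios for the three- and four-component nRMSD batches (round budget
24), `L = 12` with budget 16 for five components (where only `n` and
`M_0` are scored — the parameters that remain identifiable at that
complexity), and `10 + 10` one-/two-component scenarios (budget 150,
tolerance `1e-10`) for the rounds-to-convergence check.  The round
budgets are deliberately small: with the misassignment-repair step,
scenarios that are going to be recovered at all converge within about
five rounds, and the remaining scenarios do not move between 24 and 200
rounds.  At these sizes a
single near-unidentifiable scenario (e.g. a component of near-zero
log-width, or a tail migration change of a few percent) moves a
migration nRMSD by ~0.1; batch-level numbers are therefore noisier than
what arbitrarily large batches would give, but the qualitative ordering —
near-perfect recovery of `n` and `M_0` at every `c`, migration nRMSD
growing with `c`, times hardest — is stable across seeds.

## The synthetic-data generator

Continuous/discrete scenario sampling plus the internal `T2` simulator
*are* the data-generating conditions: they emulate what a perfectly
estimated (exact targets) or finitely sampled (T-sim targets) IICR of a
true piecewise n-island world would look like.  They do not emulate PSMC
estimation noise (spurious recent/ancient humps, interval
discretization artifacts), sequencing or phasing error, or any violation
of the island assumptions (unequal deme sizes, asymmetric gene flow,
population splits).  Passing validation therefore demonstrates that the
*inverse problem* is solved under the model's own assumptions — not that
a real genome's history is an island model.  Fitting real PSMC curves
additionally inherits PSMC's own biases, which is why `ω` and
`time_range` exist.

## Known limitations

* Models with `c ≳ 5` components are close to the identifiability edge;
  middle-component rates and times may be interchanged (misassignment)
  even at tiny distances.
* Deme sizes are fixed by bounds; within one component, size and
  migration changes are confounded in the IICR, and freeing both is out
  of scope.
* The `ms` command emitter and PSMC parser bridge to external tools; the
  package never executes them.  The migration-unit bridge is `4Nm = M`
  (the paper-scale total rate equals ms's migration parameter) while
  event times are halved (`2N` → `4N` units) — the classic pitfall,
  encoded once in `ms_command` and tested.
* `sample_discrete` supports a single deme-size value (all published
  discrete designs use `s = 1`).
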