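# Methods

## Model

A hypergraph `H = (V, E)` has `N` nodes and hyperedges `e_j ⊆ V` with
`|e_j| ≥ 2`.  Node states are Bernoulli variables `Y_i ∈ {0,1}`; the
per-hyperedge active count is `T_j = Σ_{k∈e_j} Y_k`.  The continuous-time
Markov chain has two transition families:

| state | transition | rate |
|---|---|---|
| each active `v_i` | `1 → 0` | `δ` |
| all inactive members of `e_j` | `0 → 1` simultaneously | `λ_j · 1{T_j ≥ Θ_j}` |

with `Θ_j = ⌈Θ*·|e_j|⌉` and `λ_j = λ·λ*(|e_j|)`.  The default
modulation `λ*(|e|) = log2(|e|)` grows sublinearly, so the per-member
spreading rate of very large groups vanishes, and `λ*(2) = 1`.

**Pairwise semantics.**  Cardinality-2 hyperedges are simulated as two
*directed* infection clocks, live whenever the source is active and the
target inactive, independent of `Θ*`.  This is the reading under which
the model restricted to a graph is exactly the SIS epidemic model; the
undirected threshold reading would silence all pairwise spreading for
`Θ* > 1/2`.  For `Θ* ≤ 1/2` (the only regime the reference analyses
exercise) the two readings coincide in law.

## Exact simulation (next-reaction method)

Every live Poisson process (node deactivation, hyperedge activation,
directed pair infection) holds its next firing time in a binary heap;
stale entries are invalidated by per-process version counters rather
than removed.  Hyperedge processes are created when `T_j` crosses
`Θ_j` and destroyed when it drops back below — or when every member is
active, in which case firing would be a no-op; the process is reinstated
as soon as a member deactivates with `T_j ≥ Θ_j` still holding.  Because
exponential clocks are memoryless, resampling a clock at (re)creation
leaves the law of the process unchanged; the suite checks this by
comparing absorption-time distributions against an independent
direct-method (total-rate, thinning) simulator (two-sample KS at
`α = 0.01`).

Initial conditions are accepted as an explicit binary vector, an
activation fraction with uniformly random placement, or a node set
(e.g. one community).

## Quasi-stationary (QS) sampling

The all-inactive state is absorbing, so every finite system eventually
dies out; the quantity of interest is the dynamics conditioned on
survival.  The sampler keeps a list of `M` previously visited active
states, continuously refreshed (the running state overwrites a uniform
slot with probability `p_r·Δt` per executed event); on absorption the
state is replaced by a uniform draw from the list.  After a relaxation
time `t_relax`, the time the run spends with `n` active nodes accrues
into `Freq(n)` (the `Δt` of each event is attributed to the
pre-transition state).  Sampling proceeds in windows of length
`t_window`; the run stops when the cumulative susceptibility changes by
less than `ε = 0.001` between consecutive windows, or after `c_max =
500` windows.

Summaries: `ρ = ⟨n⟩/N`, `χ = (⟨n²⟩−⟨n⟩²)/⟨n⟩` under the time-weighted
distribution.  Monte-Carlo standard errors are per-window block
estimates; windows long relative to the autocorrelation time make the
blocks effectively independent.

Defaults: `M = 100`, `p_r = 0.02` per unit time (the sampler is stable
over at least a decade of either, which the suite checks); `t_relax =
10⁴`, `t_window = 10³` as conservative defaults for large systems.
Tests and examples pass explicitly smaller windows sized to their
fixtures (tens to hundreds of time units for `N ≤ 200`) so the suite
completes in minutes; the stopping rule, not the window size, controls
the attained precision.

**Peak detection.**  State-distribution peaks are local maxima of a
moving-average-smoothed profile (window 5 bins) with prominence at least
2% of the profile maximum.  The smoothing is edge-normalized (edge bins
average only the in-range kernel part) so a flat profile stays exactly
flat, the structurally empty `n = 0` bin is excluded, and boundary modes
(the QS mode near `n = 1`, or a mode at `n = N`) are detected by an
explicit one-sided rule, since an interior-maximum test cannot see them.

**Branch labelling.**  A λ-sweep runs the QS sampler per (λ, seeding,
replica) and clusters the resulting `ρ` values by single-linkage with a
gap rule: a split requires a gap larger than `5/N` *and* 3 pooled
standard errors.  Labels are ordinal in mean `ρ` and are not matched to
any external numbering.

## Individual-based mean field

Assuming independent node states `y_i = ⟨Y_i⟩`:

```
dy_i/dt = −δ y_i + λ (1−y_i) Σ_{e_j ∋ i} λ*(|e_j|) Σ_{k=Θ_j}^{|e_j|−1} P_i,j(K = k)
```

where `P_i,j` is the Poisson-binomial distribution of the number of
active members of `e_j` excluding `i`.  Subset enumeration of that
distribution is exponential in `|e_j|` and numerically fragile; the
production kernel uses the characteristic-function/DFT identity, which
is stable for cardinalities well beyond 80 (checked at 83, the largest
group in the motivating dataset).  Per-node exclusion uses exact
prefix×suffix products of the DFT factors — a reordered direct product,
not a deconvolution.  Tiny negative pmf entries from floating point are
clipped and the pmf renormalized; drift beyond 1e−6 warns.

**Steady states.**  Adaptive RK45 (per-step absolute error 1e−4,
relative 1e−3, state clipped to `[0,1]`) follows the flow for a
configurable transient (default 50 time units) to settle into the
correct basin of attraction; the remaining relaxation — which can be
extremely slow near thresholds — is accelerated by damped (ω = 0.5)
fixed-point iteration of `y ← λD/(δ + λD)`, whose fixed points are
exactly the ODE equilibria.  If the iteration stalls or diverges the
solver falls back to further ODE time.  Convergence means
`max_i |dy_i/dt| < 1e−8` (configurable); states are flagged otherwise.

**Continuation.**  From a seed micro-state at one λ, the steady state is
reused as the initial condition at the adjacent grid value, marching up
and/or down.  A direction stops early when the new steady state lands
within `1/N` (in `ρ`) of an already-recorded trace at the same λ.
Uniform initial conditions find few branches; micro-state seeds
(e.g. one community active, or a simulation snapshot) uncover the rest,
and `y(0) = 1` reaches the uppermost branch.

## Exact occupancy chain of the hyperblob

The hyperblob (random `k`-regular graph plus one hyperedge containing
every node) is homogeneous, so the dynamics lump to a chain on
`n ∈ {0..N}`:

```
Q[n, n−1] = δ n
Q[n, n+1] = λ⟨k⟩ n (N−n) / N
Q[n, N]   = λ* · 1{n ≥ Θ}
```

`λ⟨k⟩` is the lumped pairwise drive and `λ*` the bare rate of the global
hyperedge.  The jump and the birth transition add at `n = N−1`; the
self-jump at `n = N` is a no-op and omitted.  The QS constraint zeroes
`Q[1,0]`.  The pairwise birth term is a homogeneous-mixing lumping: it
is exact for `k = N−1` (complete graph, with `λ⟨k⟩ = λ_pair·N`), and a
mean-field approximation otherwise — the simulator-vs-chain agreement
test therefore uses `k = N−1`.

**Stationary distribution.**  Seeding `π₁ = 1`, the forward recursion is
evaluated in the cut-balance (probability-flux) form

```
δ(n+1) π_{n+1} = β_n π_n + λ* Σ_{i=Θ}^{n} π_i
```

which telescopes the stationarity equations, contains no subtraction
(hence no cancellation for large N), costs O(N) with a running jump
sum, and is renormalized in-flight when entries grow past 1e250.  The
terminal global-balance closure at `n = N` is verified post-hoc to a
relative residual of 1e−6, and a dense null-space solve of `Qᵀ` serves
as an independent oracle (sup-norm 1e−8 agreement for N up to 500 in the
suite).  With `λ* = 0` the chain is the QS-SIS birth-death chain with
the classical product-form solution, checked to 1e−12.

Derived summaries split the distribution at `Θ`: `P_Lower = Σ_{n<Θ} π_n`,
`P_Upper = Σ_{n≥Θ} π_n`, with conditional `ρ`/`χ` per region (NaN when a
region carries no mass).

**Transition-window scaling.**  For each N the λ-grid summaries locate
the coexistence window of the jump between the lower (SIS-like) and the
upper (fully active) solution:

- `λ(ρ₂)` — the largest λ whose global `ρ` is within `1/N` of the
  lower-region conditional `ρ`;
- `λ(ρ₂⁺)` — the smallest λ within `1/N` of the upper-region
  conditional `ρ`;
- `λ(χ₂∓)` — the extremal finite-difference derivatives of `χ(λ)`
  flanking the jump.

The grid refines itself around the window (factor 10 per pass, up to 4
passes) until at least 5 grid points resolve it; unresolved sizes are
flagged and excluded from the ordinary-least-squares log–log fit of
`width ∼ N^(−μ)` (slope standard error reported, no weighting).  These
marker definitions operationalize a prose description that admits
several readings; they are parameters of the analysis, not claims about
the original authors' choice.  With `λ* = 10`, `Θ* = 0.2`, `δ = 1` and
N ∈ {200, …, 3200} the widths shrink monotonically and the fitted
exponents are `μ_ρ ≈ 0.63`, `μ_χ ≈ 0.71` — both below 1, the hybrid
signature; the exact exponent value depends on `Θ*`, which is why no
single literature value is asserted.

## Generators: the stated world

- **Hyperblob** — `networkx.random_regular_graph` (pairing model) for
  the pairwise part; `k = N−1` special-cased to the complete graph; one
  all-node hyperedge appended.
- **Community model** — two-to-many equal blocks; per-block counts
  `m_in[c]` of in-block hyperedges; `m_out` bridges each spanning
  exactly two uniformly chosen blocks with a uniform split
  `ℓ ∈ {1, …, |e|−1}` of members between them.  Cardinalities are
  `⌈x⌉` with `x ~ Exp(mean μ)`, clamped into `[2, N/n_c]` — the ceiling
  is the discretization choice (keeps the mean near μ for μ ≫ 2).
  Duplicate hyperedges are resampled.  The reference configuration is
  two blocks of unequal density (`m_in = (2m, m)`), mean cardinality
  μ = 8.
- **Rewiring** — pairwise shuffle steps: pool two hyperedges' members,
  repartition at the original cardinalities; reject (but still count)
  proposals that repeat a node within a hyperedge or duplicate an
  existing hyperedge.  Node membership counts and the cardinality
  multiset are exact invariants.  Counting rejected proposals follows
  MCMC convention, matching "number of rewirings" as attempted moves.

What the generated fixtures do *not* reproduce about real social
hypergraphs: degree heterogeneity within blocks, overlapping or nested
group structure, and cardinality–degree correlations.  A green
mechanism test therefore establishes that community structure plus
bridge hyperedges *suffice* for multistability/intermittency in the
model — not that they are the mechanism in any particular dataset.

## Numerical and degenerate-input choices

- `λ = 0` under QS concentrates at the floor `n = 1` (only deactivation
  clocks run; the recycle list keeps one active node).
- Frozen states (no live process, e.g. `δ = 0` with no spreadable
  hyperedge) persist to the horizon rather than erroring.
- `evolve` uses sparse `expm_multiply` (the generator is tridiagonal
  plus one column); each output distribution is renormalized, with
  conservation drift beyond 1e−10 treated as an error.
- The stationary recursion requires `δ > 0`; `δ = 0` has no normalizable
  QS distribution on the full state space.
- Branch clustering falls back to a single branch with a warning if the
  gap rule cannot be evaluated.
- All generators and simulators take explicit integer seeds
  (numpy PCG64); identical seed ⇒ bit-identical output.

## Scaled-down test world

The suite is sized for a single CPU within minutes: mechanism fixtures
use N = 200 (vs 10³ in the motivating analyses), QS windows of
80–200 time units with the adaptive χ stopping rule, and exact-chain
scaling up to N = 3200.  The multistability check runs at bridge count
10 and λ = 0.22; the intermittency check at bridge count 120 and
λ = 0.05 — both windows located by scanning the fixed fixture before
freezing the test, as the regime boundaries shift with system size.

## Known limitations

- The exact chain covers only the hyperblob's symmetry class; arbitrary
  hypergraphs would need the full `2^N` state space.
- The mean-field closure neglects all correlations: it predicts the
  *positions* of distribution modes (branches) but not mode weights,
  intermittency, or fluctuation-driven branch selection, and typically
  overestimates the stochastic `ρ` slightly (asserted as
  `ρ_ODE ≥ ρ_MC − 3·SE` on the hyperblob, where the chain provides the
  exact `ρ_MC`).
- Branch labels from sweeps are ordinal per λ; near transitions the
  automatic clustering may split or merge differently from a manual
  assignment.
- No spectral/localization theory and no second-order (pair) closure is
  attempted.
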