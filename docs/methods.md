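# Methods

## Model

Each of `n` subjects carries two feature blocks: a rough-level vector
`X_i ∈ R^q` (e.g. clinical imaging features) and a refined-level vector
`Z_i ∈ R^p` (e.g. omics features).  Every subject gets its own pair of
centers `(β_i, γ_i)`; two subjects share a rough cluster iff `β_j = β_m`
and a refined cluster iff `γ_j = γ_m`.  The estimator minimizes

```
Q(β, γ) = ½ Σ_i (‖X_i − β_i‖² + ‖Z_i − γ_i‖²)
        + Σ_{(j,m) ∈ A \ A^p} p( √(‖β_j−β_m‖² + ‖γ_j−γ_m‖²); λ₁ )
        + Σ_{(j,m) ∈ A \ A^p} p( ‖β_j−β_m‖₂; λ₂ )
```

subject to `β_j = β_m` and `γ_j = γ_m` for all must-link prior pairs
`(j,m) ∈ A^p`, where `A` is the set of all n(n−1)/2 pairs and `p(·; λ)` is
the minimax concave penalty (MCP)

```
p(t; λ) = λt − t²/(2a)   for t ≤ aλ,      aλ²/2  otherwise,
```

with concavity constant `a > 1` (default 3).  MCP shrinks small pairwise
differences exactly to zero (fusing samples into clusters) while leaving
large differences unpenalized, so big clusters separate without bias.

**Why two penalties give nesting.**  The refined difference `γ_j − γ_m`
appears only inside the first (group) penalty.  A group penalty is "all in
or all out": it cannot zero `β_j − β_m` jointly with `γ_j − γ_m` while
leaving the latter free.  Consequently `γ̂_j = γ̂_m` forces
`β̂_j = β̂_m` — the refined partition is exactly nested in the rough one.
The second penalty fuses rough levels alone, so `β̂_j = β̂_m` with
`γ̂_j ≠ γ̂_m` (same rough, different refined cluster) remains possible.

**Must-link priors.**  `A^p` must be transitively closed; raw pair lists
are closed on input (closure is the unique minimal consistent completion;
the module closes rather than rejects).  The closed set induces a partition
into blocks `F_1..F_K` (connected components plus singletons), encoded by
the n×K indicator `L`.  Constraints are enforced exactly by parametrizing
the centers over blocks — never by penalization — so prior feasibility
holds at every iteration, to machine precision.

## Algorithm

ADMM with per-pair splitting variables `ω_{jm} ≈ β_j − β_m`,
`η_{jm} ≈ γ_j − γ_m`, duals `(v, u)`, and penalty parameter `ϑ` (default
1.0; the solution at convergence is insensitive to it in this regime).
One iteration:

1. **Center update** (exact).  The augmented Lagrangian is quadratic in
   the block centers `T`; the normal equations involve
   `LᵀL + ϑ LᵀDᵀDL` where `D` is the signed pair-incidence matrix.
   Because `DᵀD = nI − 11ᵀ`, this K×K matrix is
   `c·diag(s) − ϑ s sᵀ` (`s` = block sizes, `c = 1 + ϑn`) and
   Sherman–Morrison gives the closed-form inverse
   `diag(1/(c s)) + (ϑ/c) 11ᵀ` — no factorization, O(K) per application.
   The Kronecker liftings `L ⊗ I` and `D ⊗ I` are never materialized.
2. **Fusion update** (exact).  Per pair, minimize
   `p(√(r_ω²+r_η²); λ₁) + p(r_ω; λ₂) + (ϑ/2)(‖ω−ω*‖² + ‖η−η*‖²)`.
   The objective is rotation-invariant within each block, so the solution
   is collinear with `(ω*, η*)` and reduces to 2-D in the radii.  MCP is
   piecewise quadratic; the finitely many stationary candidates of every
   smooth piece are solved in closed form (one piece needs a scalar
   bisection), boundary points added, and the global minimum picked by
   objective comparison.  Ties within 1e−12 prefer less shrinkage, for
   determinism.  Prior pairs are fixed at zero.  This enumeration is exact
   also in the non-convex regime `ϑa ≤ 1`, where a naive fixed-point
   iteration can land in the wrong basin.
3. **Dual ascent** on the pair residuals.

**Initialization.**  Two-step K-means: cluster `X` with the count chosen
by the Calinski–Harabasz index over k = 2..10 (10 restarts, seeded), then
cluster `Z` inside each rough cluster the same way (one refined cluster
when a rough cluster has < 3 members, where the index is undefined).  Each
prior block is then reassigned to its majority cluster at both levels
(ties toward the lowest label) and centers recomputed, which establishes
feasibility with minimal relabeling.  `ω, η` start at the initial
differences, duals at zero.

**Convergence.**  Primal residual norm ≤ `tol·√(|A|(q+p))` with
`tol = 1e-4` (default) and at most 500 iterations.  The dual residual is
not gating; cluster structure is read from the fusion variables, which
primal feasibility controls.  One degenerate regime needs care: when
*every* free pair sits in the flat MCP region the prox is the identity,
the primal residual vanishes identically, and plain ADMM would creep
toward the optimum at a slow geometric rate.  There the penalties are
locally constant, so the exact minimizer is the block-mean projection of
the data; the solver jumps to it directly and accepts it if the flat
regime is self-consistent.  This makes the λ→0 limit (`β̂ = X`, all
singletons) exact.

**Cluster extraction.**  Merge graphs come from the fusion variables —
rough edges where `‖ω̂‖ ≤ 1e−8` plus prior pairs, refined edges
additionally requiring `‖η̂‖ ≤ 1e−8` — and clusters are their connected
components.  Reading "distinct columns of β̂" directly would be ill-posed
at finite ADMM precision; `ω̂` is exact sparsity by construction.  Refined
edges are a subset of rough edges, so nesting holds structurally.
Reported centers are within-cluster means of `β̂`/`γ̂` (averaging removes
sub-tolerance jitter).

## Tuning

`(λ₁, λ₂)` minimize the modified BIC

```
BIC = log{ (1/n) Σ_i (‖X_i − β̂_i‖² + ‖Z_i − γ̂_i‖²) }
    + C_n (log n / n) (K̂₁ + K̂₂),        C_n = log(log n),
```

over log-spaced grids spanning [0.05, 2.0] times each penalty's natural
scale — `√((q+p)/n)` for λ₁ (joint (q+p)-dimensional differences) and
`√(q/n)` for λ₂ (q-dimensional rough-level differences); default 8×8, the
replication harness uses 5×5, which selects the same models on the study
scenarios at a third of the cost.  Scaling λ₂ by its own, smaller
dimension is load-bearing: the flat MCP constant `aλ²/2` is paid by every
one of the n(n−1)/2 pairs, so a λ₂ much beyond the rough-level fusion
range makes the all-merged configuration *globally* favorable (the BIC
cluster penalty is only O(log n/n) per cluster and cannot compensate),
and selection destabilizes.  `C_n = 1` and `C_n = log n` are also
available.  Two further guardrails:

- A saturated fit (zero residual, e.g. the exact λ→0 solution) makes the
  log term −∞; such fits are recorded with a sentinel and never selected —
  their "fit" measures shrinkage, not clustering.
- Every grid fit is warm-started from the shared K-means initialization
  rather than chained from a neighboring grid solution.  The objective is
  non-convex; chaining lets the fully-fused corner's local minimum
  propagate across the whole grid (observed on the study scenarios).
  Selected models match independent cold runs (tested).

Ties prefer the lexicographically smaller `(λ₁, λ₂)`.

## Synthetic scenarios

The generator reproduces the simulation study conditions: `n = 120`,
`q = 6`, `p = 30`, `σ² = 1`, `ρ = 0.3`, refined labels uniform on
`{1..K₂}`.  Rough centers are `(4/5)μ` times ±1 sign blocks over thirds of
`q`; refined centers are `μ` times ±1 blocks over halves or thirds of `p`
(three Gaussian layouts with (K₁,K₂) = (2,4), (2,6), (3,6); `Σ_Z`
diagonal, AR(ρ) or banded).  The half-moon scenarios replace the first two
X dimensions with radius-4 arcs about `(−ν, 0.2)` (upper, angle uniform on
[0, π]) and `(ν, −0.2)` (lower, [π, 2π]) plus N(0, 0.1²) noise, the
remaining four dimensions Gaussian at `(4/5)μ(∓1,∓1,±1,±1)`; `μ = 1`,
`Σ_Z = I`.  The hierarchy-violation scenario has 2 rough and 5 refined
clusters with the middle refined cluster (center `0_p`) straddling both
rough clusters — its members draw their rough label at random.

**Priors.**  `⌊τ·N₀⌋` pairs are drawn uniformly from the `N₀` true
same-refined-cluster pairs and transitively closed (the pair-set contract
requires closure; the raw draw is also exposed so both readings are
testable).  Study levels: τ = 4% ("Prior1") and 8% ("Prior2").
Mis-specified priors merge the ten smallest prior blocks (singletons
included, ranked by size then smallest member) into one block of ten
unrelated samples — 45 wrong must-link pairs.  Merging the ten *largest*
blocks is implemented too, but as hard equality constraints that weld ~40
samples across all true clusters it caps the attainable rough ARI near
0.4; the mis-specification arms of the replication study therefore use
the 10-sample merge.

**What the generator does not emulate:** real imaging/omics pipelines
(feature extraction, prescreening, PCA), non-Gaussian noise, missing
values, or informative prior selection (priors are sampled uniformly from
true pairs).  Passing tests show the estimator recovers planted
hierarchical structure under these stylized conditions, not performance on
real cohorts.

## Evaluation

- **ARI** is implemented in its pair-counting form
  `2(TP·TN − FP·FN) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN))` — the form the
  study tables use — with 0 returned when the denominator vanishes (e.g.
  one-cluster truth vs all singletons).  A cross-check against the
  classical Hubert–Arabie implementation is part of the test suite as a
  diagnostic, never a substitute.
- **Center error** is `((1/(nd)) Σ_i ‖est_i − true_i‖²)^{1/2}` — an RMSE,
  implemented exactly as the tables print it (under the "MSE" name).
- **SI** is the fraction of pairs on which two labelings agree about
  same-vs-different cluster; the leave-m-out stability procedure removes
  `m` random subjects (prior status ignored), retunes, and compares
  against the full-data labeling restricted to the survivors.

## Baseline

Two-step convex clustering: `½Σ‖x_i−u_i‖² + λ Σ_{j<m} ‖u_j−u_m‖` (L2
group or L1 elementwise fusion, uniform weights) by the same ADMM
machinery with the convex prox, on X first, then on Z within each rough
cluster; refined labels renumbered globally.  Per-step λ is chosen by the
step-restricted modified BIC over a grid spanning [1, 20] times
`σ̂·√d/n` (L2) or `σ̂/n` (L1) — the scale at which the accumulated pull of
~n uniform-weight pairs offsets a noise-sized deviation.  Near-saturated
step fits (K > n/2) are never selected, for the same reason as above.
With uniform weights the fusion path on overlapping Gaussian clusters can
jump from all-singletons to one cluster; this is a known property of
uniform-weight convex clustering and the regime in which the main method's
advantage is largest.

## Scaled study configuration

Replication runs use 20 replicates (tests) or 10 (acceptance script)
instead of 100, the 5×5 grid, primal tolerance 5e−4 and max 200
iterations.  These sizes were chosen as the smallest at which scenario
means stabilize to well within the comparison tolerances; selections are
unchanged versus the full-precision settings on the study scenarios.
Per-replicate seeds derive from the base seed as `base + r` (data) and
`base + 10⁶ + r` (prior sampling), so prior arms share each replicate's
data.

## Known limitations

- The objective is non-convex; the solver finds a local minimizer whose
  quality depends on the two-step K-means initialization.  All reported
  study conditions are well within the regime where this is reliable.
- No sparsity/feature selection: all q + p features inform the clustering.
- Must-link constraints are hard; a wrong prior pair cannot be overridden
  by data (by design — see the mis-specified-prior results).
- Cannot-link constraints are not supported.
- BIC-based tuning assumes the residual scale is comparable across the
  grid; the saturation sentinel handles the one regime where it is not.
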