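# pchclust

Hierarchical heterogeneity analysis of two-block data with must-link
priors: convex-clustering-style penalized fusion that jointly identifies a
**rough** clustering from one feature block (X, e.g. clinical imaging
features) and a **refined** clustering from a second block (Z, e.g. omics
features), with the refined partition *exactly nested* in the rough one.

Typical users: biostatisticians analyzing cancer cohorts where imaging
features define coarse subtypes, molecular features define sub-subtypes
within them, and a handful of subjects carry extra annotations that pin
some pairs to the same subtype in advance.

## Model

Each subject `i` has its own centers `(β_i, γ_i)`; clusters are the groups
of subjects sharing a center.  The estimator minimizes

    ½ Σᵢ (‖Xᵢ − βᵢ‖² + ‖Zᵢ − γᵢ‖²)
      + Σ_{(j,m)∈A∖Aᵖ} p(√(‖βⱼ−βₘ‖² + ‖γⱼ−γₘ‖²); λ₁)
      + Σ_{(j,m)∈A∖Aᵖ} p(‖βⱼ−βₘ‖₂; λ₂)
    s.t.  βⱼ = βₘ, γⱼ = γₘ  for all must-link pairs (j,m) ∈ Aᵖ,

where `p(·; λ)` is the minimax concave penalty (MCP) and `A` is the set of
all sample pairs.  The group penalty on the joint difference is "all in or
all out": it cannot merge two subjects at the refined level without also
merging them at the rough level, which is what guarantees nesting.  The
optimizer is ADMM with an exact closed-form center update (Sherman–Morrison
on the K×K prior-block system) and an exact enumerated prox for the nested
MCP pair subproblem.  `(λ₁, λ₂)` are selected by a modified BIC with
`C_n = log(log n)`.  Must-link priors are enforced as hard equalities via a
block parametrization, never by penalization.

## Worked example

Generate the (3, 6)-cluster Gaussian scenario (n=120, q=6, p=30, AR
covariance, center scale μ=1.2), sample 8% of the true same-cluster pairs
as a must-link prior, and tune:

```python
import pchclust as pc

data, truth = pc.generate(pc.ScenarioConfig(scenario="sim3", mu=1.2,
                                            cov_Z="AR", seed=1))
prior = pc.sample_prior(truth, tau=0.08, seed=11)
grid = pc.default_grid(data.n, data.q, data.p, size=5)
config = pc.SolverConfig(seed=0, tol_primal=5e-4, max_iter=200)
state, result, table = pc.tune(data, prior, grid, config)

print("K1=%d K2=%d" % (result.K1, result.K2))
print("ARI rough  = %.4f" % pc.ari(truth.rough_labels, result.rough_labels))
print("ARI refined= %.4f" % pc.ari(truth.refined_labels, result.refined_labels))
print("gamma RMSE = %.4f" % pc.mse_centers(state.gamma, truth.gamma_star))
```

prints

```
K1=3 K2=6
ARI rough  = 0.9252
ARI refined= 0.9394
gamma RMSE = 0.3091
```

The tuned model recovers the true cluster counts (3 rough, 6 refined); the
adjusted Rand indices compare the estimated partitions with the truth
(1 = exact recovery, ≈0 = random), and the center RMSE measures how close
the per-sample refined centers `γ̂` sit to the true ones.  Dropping the
prior (`prior=None`) lowers the ARIs to ≈0.85/0.88 — the must-link pairs
buy real accuracy.

The same operations are available from the shell:

```
pchclust simulate --scenario sim3 --mu 1.2 --cov-z AR --tau 0.08 --out sim/
pchclust tune --x sim/X.csv --z sim/Z.csv --prior sim/prior_pairs.tsv --out fit/
pchclust evaluate --labels fit/labels.csv --truth sim/truth.csv
pchclust replicate --scenario sim3 --mu 1.2 --cov-z AR --replicates 20
pchclust stability --x sim/X.csv --z sim/Z.csv --m 5 -r 10
```

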