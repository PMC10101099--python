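# microstab

Stability analysis of longitudinal microbiota time series under
generalized Lotka-Volterra (gLV) dynamics.

`microstab` is for microbial ecologists who have a weekly (or otherwise
regular) OTU count table per participant — e.g. repeated oropharyngeal or
gut swabs — together with sample metadata and a phylogenetic tree, and who
want to go beyond diversity summaries and ask *dynamical* questions: is
each participant's core community locally stable? Is it permanent
(globally stable, no species driven extinct from any interior state)? Is
it resistant to invasion by a new taxon? The package provides the whole
path from raw counts to those verdicts, plus the community-ecology
statistics that surround such an analysis, and a synthetic-data module
with known ground truth so every stage is testable offline.

## The model and statistics

Each participant's core community (OTUs exceeding a 0.001 relative-
abundance detection threshold in ≥ 85% of their samples) is modelled by
the Ricker map, the discrete-time analogue of gLV dynamics:

    x_i(t+1) = x_i(t) · exp( r_i + Σ_j A_ij x_j(t) + ε_i(t) )

Because the log-increment is linear in the lagged abundances, the
interaction matrix **A** and growth rates **r** are inferred per taxon by
sparse forward-stepwise regression with bagging (median held-out error
over random train/test splits; median coefficients; never-selected
predictors stay 0).

From the inferred model:

* **local stability** — dominant eigenvalue λ_max of the Jacobian
  J = diag(x*)·A at the interior equilibrium x* = −A⁻¹r; stable iff
  λ_max < 0;
* **permanence** — Jansen's average-Lyapunov-function condition: a weight
  vector p > 0 with Σ_i p_i (r_i + (A·x̂)_i) > 0 at every boundary
  equilibrium x̂, found by linear programming and re-verified before being
  reported (together with a dissipativity check);
* **invasibility** — dominant eigenvalue of the Jacobian augmented with
  an invader with zero interaction rows/columns and growth rate r_inv.

Around this core the package implements, from their definitions:
Renyi-Hill alpha diversity (q = 0, 1, 2); Bray-Curtis, Hellinger and both
UniFrac dissimilarities (per-branch evaluation, any rooted tree); LCBD
(per-sample contributions to beta diversity via Gower centering); NRI/NTI
(phylogenetic clustering vs a richness-preserving null over the top-1,000
most abundant OTUs); and BVSTEP (minimal OTU subset whose dissimilarity
structure rank-correlates at ρ ≥ 0.95 with the full table). Read-depth
filtering (< 5,000 reads) and rarefaction precede all diversity
computations. See `docs/methods.md` for the full specification of every
algorithm and its numerics.

## Worked example

Infer a model from synthetic ground truth and assess its stability:

```python
import numpy as np
import microstab as ms
from microstab.synthetic import perturbation_series

# ground truth: 5 taxa, stable interior equilibrium
model, x_star = ms.random_stable_glv(5, seed=7)

# observed data: 15 perturbation-relaxation epochs, multiplicative noise
series = perturbation_series(model, x_star, n_epochs=15, steps=10,
                             noise_sigma=0.02, seed=7)

fit = ms.limits_infer(series, ms.InferenceConfig(n_bags=50, seed=7))
print("true diag:", np.round(np.diag(model.A), 3))
print("fit  diag:", np.round(np.diag(fit.A), 3))
print("pearson:", round(float(np.corrcoef(fit.A.ravel(),
                                          model.A.ravel())[0, 1]), 3))

rep = ms.assess_stability(fit, "P01")
print(rep.dominant_eigenvalue, rep.locally_stable, rep.permanent,
      rep.invasible)
```

prints

```
true diag: [-0.68  -0.903 -0.55  -0.541 -0.994]
fit  diag: [-0.61  -0.798 -0.524 -0.587 -0.93 ]
pearson: 0.988
-0.03480090066511337 True True False
```

i.e. the self-limitation terms are recovered to within the noise, the
inferred matrix correlates with truth at r = 0.988, and the inferred
community is locally stable (λ_max ≈ −0.035 < 0), carries a verified
permanence certificate, and is not invasible by a neutral (r_inv = 0)
invader.

The same analysis runs end-to-end from files via the CLI:

```
microstab simulate --participants 30 --weeks 30 --seed 1 --out fixture/
microstab run --config run.yaml     # filter → rarefy → diversity → LCBD
                                    # → NRI/NTI → BVSTEP → core → inference
                                    # → stability/permanence/invasibility
```

producing per-sample `alpha.tsv`, `lcbd.tsv`, `ses.tsv`, four
dissimilarity matrices, `bvstep.json`, one stability report per
participant under `reports/`, and a `manifest.json` with the config hash,
per-stage counts and smoker/nonsmoker group summaries. Reruns with the
same config and seed are byte-identical.

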