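# Methods

`microstab` analyses longitudinal microbiota count data through an
ecological-stability lens: it filters and summarizes the community data
(diversity, uniqueness, phylogenetic structure, subset selection), infers a
per-participant generalized Lotka-Volterra (gLV) interaction model from the
weekly time series of that participant's core OTUs, and then interrogates
the inferred model for local stability, permanence (global stability) and
invasibility. This note records the models, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Dynamical model

The community state is the vector x of core-OTU abundances, measured as
fractions of the whole sample. Between-week dynamics are modelled by the
Ricker map, the standard discrete-time analogue of gLV dynamics:

    x_i(t+1) = x_i(t) · exp( r_i + Σ_j A_ij x_j(t) + ε_i(t) ),

with r_i the intrinsic per-week growth rate, A_ij the per-capita effect of
taxon j on taxon i's growth rate (A_ii < 0: self-limitation), and
ε ~ N(0, σ²) a multiplicative environmental noise term. The Ricker form is
chosen over an Euler discretization because its log-increment

    ln x_i(t+1) − ln x_i(t) = r_i + Σ_j A_ij x_j(t) + ε_i(t)

is *exactly* linear in the lagged abundances, which is the regression the
inference uses; the two discretizations coincide for small per-step
changes. Abundances below an extinction floor (default 1e-6) are set to 0,
which is absorbing; this prevents log-of-zero artifacts downstream.

## Community preparation

* Samples with fewer than 5,000 reads are discarded (strict `<`).
* Remaining samples are rarefied (uniform subsampling without
  replacement, implemented as a multivariate hypergeometric draw) to a
  common depth, by default the minimum library size of the retained
  samples. Alpha diversity is computed only on rarefied tables
  (order: filter → rarefy → diversity).
* The per-participant core microbiota is the set of OTUs whose relative
  abundance reaches a detection threshold (default 0.001) in at least
  ⌈prevalence · T⌉ of the participant's T samples. The prevalence default
  is 0.85 and is exposed as a parameter in [0.85, 0.92]; the ceiling rule
  is chosen for reproducibility. Core abundances remain fractions of the
  whole sample — they are *not* renormalized to the core — so gLV states
  are comparable across participants.

## Diversity statistics

* **Hill numbers** of order q: q=0 richness, q=1 exp(Shannon), q=2
  inverse Simpson, computed from their definitions; they are
  non-increasing in q on every sample.
* **Dissimilarities**: Bray-Curtis on counts; Hellinger as the Euclidean
  distance between square-rooted proportion vectors; unweighted UniFrac as
  (branch length unique to one sample) / (branch length in either); and
  normalized weighted UniFrac, Σ_b l_b|p_A(b) − p_B(b)| / Σ_b l_b(p_A(b) +
  p_B(b)), with p(b) the fraction of reads descending from branch b. The
  UniFrac variants are computed by direct summation over branches, which
  works on arbitrary (including multifurcating) rooted trees; on strictly
  bifurcating trees the results agree with scikit-bio to 1e-10, and a
  per-branch brute-force evaluator in the test suite provides an
  implementation-independent oracle.
* **LCBD** (local contribution to beta diversity): Gower-center the
  squared dissimilarity matrix, G = −½·C·D²·C; LCBD_i = G_ii / tr(G).
  Values sum to 1 by construction; the trace must be positive (identical
  samples are rejected as "no beta diversity").
* **NRI/NTI**: presence/absence MPD and MNTD of each sample against a
  richness-preserving null (999 draws by default) from the pool of the
  top-1,000 most abundant OTUs (ties broken lexicographically). The index
  is the negated standardized effect size; when the null distribution has
  zero spread (sample = whole pool; star tree) the index is flagged
  undefined rather than fabricated. Per-sample RNG seeds are derived by
  hashing the sample id with the master seed, so results are independent
  of sample order.

## BVSTEP

The subset search maximizes the Spearman rank correlation ρ between the
condensed dissimilarity vector of an OTU subset and that of the full
(top-k restricted) table. Forward steps add the best single OTU
(lexicographic tie-break), each add strictly increasing ρ; backward sweeps
drop any OTU whose removal costs less than 1e-6 in ρ (the most recent
addition is exempt, which precludes add/drop cycles); the search stops at
ρ ≥ 0.95 (default) or when no improving move exists, returning
`converged=False` in the latter case. For Bray-Curtis the subset
dissimilarities decompose into per-OTU pairwise numerator/denominator
contributions, so candidate moves are evaluated incrementally. For
Hellinger the square-root-proportion transform is applied once to the full
table and subsets are column selections of the transformed matrix —
renormalizing proportions within each candidate subset would make every
single-OTU subset degenerate (all proportions 1).

## Interaction inference

Per participant and per taxon i, the regression target is
y_i(t) = ln x_i(t+1) − ln x_i(t) over consecutive-week transitions where
both abundances are positive; predictors are the lagged abundances x_j(t)
plus an intercept (→ r_i). Gaps in the weekly series break the transition
chain — a one-step map is never regressed across a missed week. Zero
abundances are excluded per-taxon rather than pseudo-counted.

The estimator is a bagged forward-stepwise regression: the transitions are
split into train/test halves n_bags times (default 100); the self-term
x_i(t) is always in the model; the candidate predictor minimizing the
median held-out mean squared error is admitted if its relative improvement
exceeds a threshold (default 0: any improvement); final coefficients are
the per-coefficient median of the per-bag ordinary-least-squares fits, and
never-admitted predictors keep A_ij = 0. Rank-deficient bags are dropped.
Participants need at least 9 samples (default `min_samples`); shorter
series are skipped with a logged reason. Raising the improvement threshold
can only remove predictors, so sparsity is monotone in it.

A note on identifiability: a single noiseless trajectory relaxing to
equilibrium eventually varies along essentially one direction of state
space, leaving the lagged-abundance design nearly collinear. The
parameter-recovery tests therefore use repeated perturbation-relaxation
epochs (`perturbation_series`): the community restarts at the equilibrium
jittered by a lognormal factor (log-sd 0.5, i.e. ~1.6-fold excursions,
comparable to week-to-week fluctuation in real longitudinal microbiota
data) and relaxes for 10 weeks, with week gaps separating epochs. Twenty
such epochs (220 samples) make every interaction identifiable: recovery is
exact (≈1e-15) without noise, and with σ = 0.01 noise the inferred matrix
correlates with truth at r ≈ 0.996 with ~85–97% sign agreement on true
nonzero entries across seeds.

## Stability analysis

* **Equilibrium**: x* solves A x* = −r (rejecting condition numbers above
  1e12); feasible means all entries strictly positive. Infeasible
  equilibria are flagged, never clamped; stability quantities for them are
  evaluated at the clipped state with the flag preserved.
* **Local stability**: continuous-time gLV Jacobian J = diag(x*)·A (a
  taxon at zero abundance contributes a decoupled row whose diagonal is
  its invasion rate). The verdict is λ_max(J) < −1e-9, with
  |λ_max| ≤ 1e-9 reported as marginal. Because the "eigenvalues of the
  interaction matrix" convention is ambiguous in the literature, the
  dominant eigenvalue of A itself is reported alongside.
* **Permanence** is certified by Jansen's sufficient condition: a weight
  vector p > 0 with Σ_i p_i (r_i + (A x̂)_i) > 0 at every boundary
  equilibrium x̂. Boundary equilibria are enumerated over all proper
  subsets (2^n; capped at n = 20 with an explicit error), keeping
  non-negative restricted solutions and deduplicating at 1e-10. The LP
  uses p_i ≥ 1 (the condition is scale-invariant in p) and a strictness
  margin δ = 1e-6; any returned certificate is re-verified against every
  constraint at margin δ/2 before being reported. Permanence additionally
  requires the dissipativity proxy: every A_ii < 0 with finite
  single-species carrying capacities. The condition is sufficient, not
  necessary — an infeasible LP yields `permanent=False` with no
  certificate, never a counter-claim.
* **Invasibility** follows the zero-rows/columns convention: the invader
  neither affects nor is affected by residents, so the augmented Jacobian
  is block diagonal — the resident spectrum plus the invader's growth
  rate r_inv at the resident equilibrium. With the literal convention
  (r_inv = 0) the augmented dominant eigenvalue is exactly 0, i.e.
  non-invasible at any positive tolerance; invader traits (r_inv,
  a_inv_inv) are therefore exposed as parameters rather than guessed.

## Synthetic data

`make_study_fixture` emulates the structure of a weekly oropharyngeal
swab study: 30 participants (40% smokers), 30 weekly samples each, a
shared pool of 50 OTUs on a random Kingman-coalescent tree, and
per-participant core communities of 10 OTUs following a stable gLV model
(equilibria drawn at 2–15% relative abundance, interaction strengths
N(0, 0.5²) at connectance 0.3, growth rates set to place the equilibrium)
with multiplicative noise σ = 0.05, sequenced by multinomial sampling at
library size 10,000. Metadata flags 5% of weeks as cold and 3% as
antibiotics. Stable models are obtained by rejection: candidates are
redrawn until the Ricker map is locally stable and non-marginal at the
interior equilibrium.

What the generator does **not** emulate: compositional closure against a
variable non-core background (all reads fall on the pool), overdispersion
beyond multinomial sampling, taxon gains/losses, aligned real taxonomies,
or any systematic smoker/nonsmoker difference — the smoking labels are
exchangeable, so group comparisons on synthetic data test machinery, not
biology. Passing tests demonstrate correctness of the algorithms under
the stated model, not that real oropharyngeal dynamics are gLV.

## Problem sizes and runtime

The shipped test battery uses: n = 10 taxa / 220 samples for parameter
recovery; 100 random 3–5 taxon models × 10 starts × 10⁴ noiseless steps
for permanence soundness (the certificate must never be contradicted by
simulation; misses in the other direction are allowed, as the condition
is only sufficient); 50 models for the stability-simulation concordance
(models with |λ_max| < 1e-3 are excluded, since near-marginal
linearization predicts nothing about finite perturbations); and the full
30 × 30 study fixture run end-to-end twice to confirm byte-identical
reruns. The whole suite completes in a few minutes on one CPU.

## Known limitations

* Permanence is checked against the continuous-time condition while the
  data-generating map is discrete; for the gentle weekly dynamics used
  here (per-step log changes ≲ 0.1 near equilibrium) the two agree, and
  the simulation cross-check enforces that agreement empirically.
* The LIMITS-style estimator assumes one-step transitions on relative
  abundances; compositional renormalization introduces a model mismatch
  that grows with the variance of total core abundance.
* BVSTEP is a greedy heuristic; the exhaustive-optimum guarantee is only
  verified at desk scale (10 OTUs).
* The dissipativity check is an operational proxy (strict
  self-limitation), not a Lyapunov-function proof of a trapping region.
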