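# Methods

## The model

Counts for a sample with K taxa are multinomial given a composition
p ∈ 𝒮_K.  Given a rooted full binary tree over the taxa, the multinomial is
equivalent to independent binomials at the d = K−1 interior nodes: if y(A)
is the total count in the subtree rooted at A, then

    y(A_l) | y(A), θ(A) ~ Binomial(y(A), θ(A)),

where θ(A) is the relative abundance of the left subtree within A.  The
logistic-tree normal (LTN) model places a multivariate Gaussian on the node
log-odds ψ(A) = logit θ(A):

    ψ = tlr(p) ~ MVN(μ, Σ).

Unlike the Dirichlet-tree multinomial (DTM), which forces independent Beta
branch probabilities and hence only K−1 scalar dispersion parameters, Σ is
unrestricted, so taxa covariance is modeled freely while the binomial
factorization keeps computation local to tree nodes.

Pólya-Gamma augmentation w_i(A) | y_i(A), ψ_i(A) ~ PG(y_i(A), ψ_i(A)) makes
the binomial-logistic likelihood conditionally Gaussian in ψ with precision
contribution w and linear term κ_i(A) = y_i(A_l) − y_i(A)/2, so every full
conditional in the hierarchy is conjugate and the model is fit by blocked
Gibbs sampling.

Zeros need no explicit inflation component: per-taxon ("within-OTU") zeros
arise from large |μ(A)| on the taxon's ancestors, and per-sample
("within-sample") zeros from large marginal variances of ψ(A).  The
`sparsity_sweep` utility reproduces both monotone responses, and the tests
assert them.

## Priors and samplers

**Base model** (`gibbs_fit_ltn`).  Cycle: (1) w ~ PG(y, ψ) elementwise;
(2) ψ_i joint MVN with precision Ω + diag(w_i); (3) μ conjugate MVN under a
MVN(0, τ²I) hyperprior, τ² = 100 (proper but diffuse; the node log-odds of
microbiome data live well inside ±10); (4) Ω = Σ⁻¹ by the column-wise block
Gibbs sampler for the graphical-lasso prior

    p(Ω|λ) ∝ ∏_{j<k} DE(ω_jk | λ) ∏_j Exp(ω_jj | λ/2) 1{Ω ≻ 0},

with λ = 10 by default.  Laplace terms are expanded as normal scale
mixtures with exponential mixing; each column's off-diagonal block then has
a Gaussian conditional and the Schur complement of the diagonal a Gamma
conditional, which preserves positive definiteness by construction.  The
sweep maintains the running inverse through partitioned-inverse identities
(O(d²) per column plus one (d−1)-Cholesky).  Nodes with y_i(A) = 0
contribute no likelihood — w = 0 and κ = 0 — so their log-odds are drawn
from the conditional prior; no pseudo-counts are ever added.

**Pólya-Gamma draws** (`polya_gamma`).  PG(1, c) uses Devroye's exact
alternating-series rejection sampler; integer b sums b exact draws.  Inside
the Gibbs loops, entries with b > 64 (subtree counts can reach the
sequencing depth) use a Gaussian matched to the exact mean and variance,

    E[w] = (b/2c) tanh(c/2),   Var[w] = b(sinh c − c)/(4c³ cosh²(c/2));

PG(b, c) is a b-fold convolution, so at b = 64 its skewness is ≈ 2% of a
unit-variance scale and the approximation error is far below Monte-Carlo
noise in any chain of realistic length.  The cutoff is an argument
(`pg_exact_max`) and the scalar `pg_draw` is always exact.  Tests pin the
sampler to the moment identities and check the two paths against each other
at a b where both are feasible.

**Mixed-effects differential abundance** (`gibbs_fit_da`).  For sample i
with group s_i ∈ {0,1}, covariates z_i (intercept included, so the global
mean is absorbed into β and α is a pure group contrast), and subject g_i:

    ψ_i = α s_i + βᵀ z_i + γ_{g_i} + ε_i,   ε_i(A) ~ N(0, σ²_ε(A)).

Priors: spike-and-slab α(A) ~ (1−π(A)) δ₀ + π(A) N(0, 1/φ_α) with
π(A) ~ Beta(m, 1−m) and φ_α ~ Gamma(t, u) (defaults t = 2, u = 1);
β ~ N(0, c·n (ZᵀZ)⁻¹) per node with c = 50; γ_g ~ MVN(0, Σ_re) with the
same graphical-lasso prior on Σ_re⁻¹ (a diagonal-precision mode is provided
as a DTM-style proxy); σ²_ε(A) ~ InvGamma(2, 1).  The inclusion odds for
α(A) are closed-form because the slab integrates analytically against the
Gaussian pseudo-likelihood of the group-1 residuals.  π(A) is updated
explicitly (conjugate Beta) rather than collapsed.

Testing:  PMAP(A) = Pr(α(A) ≠ 0 | Y) and PJAP = Pr(α ≠ 0 | Y) are the
fractions of retained draws with the respective event.  The prior inclusion
probability m is either set directly (m = 0.05 for taxa identification) or
calibrated so that the prior global-null probability is p₀:
m = 1 − p₀^{1/(K−1)}.  Nodes are reported by sorting PMAPs and selecting
the largest prefix whose average (1 − PMAP) — the posterior expected FDR —
stays below the target c; ties at the threshold are all selected, which can
push the realized average slightly above c (a deliberate, documented
choice favoring completeness of the report).  Signs of α(A) indicate which
child gained relative abundance in group 1.

**Posterior predictive checks.**  The spike-and-slab is replaced by a plain
Gaussian slab (`spike_slab=False`), and 500 replicated count tables are
drawn at the observed depths; 95% envelopes of per-OTU and per-sample zero
proportions are compared with the observed values.

## Synthetic data

The generator defaults are the benchmark study conditions:

- **Logistic-normal (ilr) data**: η_i ~ MVN(m, Ω₀⁻¹) on the tree's ilr
  coordinates, p_i = ilr⁻¹(η_i), X_i ~ Multinomial(10⁵, p_i), n = 200,
  with components of m drawn N(0, 16).  Ω₀ follows one of three structures:
  *hub* (3 hubs; hub edges w.p. 0.7, other pairs 0.2, entries ±0.3),
  *block* (10 equal blocks; within 0.5, between 0.2, entries ±0.3), and
  *sparse* (a dense-ish p₁ = ⌊3√d⌋ block with Unif ±[0.5, 1] entries at
  edge probability 0.3, identity elsewhere).  Diagonals are the absolute
  off-diagonal row sum plus 0.1 (strict diagonal dominance, hence positive
  definite deterministically).  Since clr(ilr⁻¹(η)) = Vᵀη for the
  orthonormal basis V, the true clr covariance is Vᵀ Ω₀⁻¹ V in closed form.
- **DTM data**: independent Beta(μν, (1−μ)ν) branch draws, then one
  multinomial per sample — the restrictive-covariance stressor.
- **Signal injection**: counts of K* taxa drawn from the 20 most abundant
  (mean per-sample relative abundance) are multiplied by (1 + a*) in
  group-1 samples and rounded to integers; the grid pairs K* = 1 with
  a* ∈ {0.5, 2, 4} and K* = 8 with a* ∈ {0.5, 0.75, 1}.
- **Longitudinal cohort** (`simulate_da_cohort`): ψ_i = μ + γ_g + ε_i with
  γ_g ~ N(0, 0.7²I), ε ~ N(0, 0.7²I), μ ~ N(0, 1.5²) per node, 33 subjects
  × 10 samples, log-normal depths with median 30k — a 16S infant-cohort
  scale (≈ 20% zero cells at K = 50).  It deliberately omits features of
  real cohorts — age trajectories, batch effects, taxon-specific
  overdispersion beyond the latent Gaussian, compositional artifacts of
  bioinformatic pipelines — so passing tests demonstrate correctness of the
  inference under the model class, not robustness to everything real data
  can do.  (The injection experiments partially cover misspecification:
  multiplicative count signals do not follow the tree.)

## Evaluation

Estimated clr correlations are obtained generatively: draw ψ ~ MVN(μ̂, Σ̂)
from posterior means, invert the tlr, clr-transform, and take the
Monte-Carlo correlation (10⁴ draws by default).  Losses against the truth
are Frobenius, operator L1 (max absolute column sum), entrywise L∞, and
spectral norms of the difference.  Zero-pattern fit uses the two-sample
Kolmogorov-Smirnov distance between per-taxon zero-proportion
distributions.

## Numerical choices and scales

- Node order is DFS preorder; the left child is the first child in Newick
  order; multifurcations are resolved by deterministic left-laddering;
  branch lengths are ignored.
- `tlr_forward` raises on zero subtree mass by default; an explicit
  `pseudo_mass` flag adds 1e-10 of the total.  The samplers never need it —
  they operate on counts, not empirical compositions.
- Gibbs initialization: ψ from empirical logits with half pseudo-counts,
  Ω = I; single chain, seed mandatory.
- Default chain lengths are 10,000 iterations with 5,000 burn-in.  The test
  suite runs scaled-down chains chosen for desk-scale wall time: parameter
  recovery at d = 7 uses 4,000 iterations; the K = 50 covariance rerun uses
  10 replicates × 2,000 iterations at n ∈ {40, 100}; differential-abundance
  power uses the 33×10 cohort at 1,500 iterations and null calibration 20
  replicates of a 15×6 cohort at 1,000 iterations.  These sizes are stated
  in the corresponding tests.
- The Geweke-style joint-consistency test alternates the model's posterior
  updates with data re-simulation and checks that the μ chain reproduces
  its own prior — a standard "getting it right" construction that catches
  wrong conditional algebra.

## Known limitations

- The latent-factor noise extension (low-rank residual covariance) and the
  graphical-horseshoe prior are not implemented; the precision-prior
  interface (`sample_glasso_precision`, `sample_diagonal_precision`) is the
  seam where an alternative would plug in.
- Non-integer PG shapes are rejected rather than sampled (the tree
  likelihood only ever needs integer counts).
- `fdr_select` reports nodes, not taxa; mapping node discoveries to taxa is
  intentionally left to the analyst because a node finding concerns the
  *split*, not either child alone.
- Interaction terms between the group label and covariates are out of
  scope.
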