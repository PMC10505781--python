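# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `ssrrm`, at the
level a user would need to interpret its output or extend it.

## 1. The random regression model

Repeated measurements of a growth-type trait between 0 and 60 months of
age are modeled with a quadratic random regression on normalized Legendre
polynomials:

* fixed effects: herd-year class, birth-month class, and a fixed
  regression of order 4 (`φ_0..φ_4`) describing the population mean curve;
* random effects: an additive-genetic coefficient vector `u_l ∈ R³` per
  animal with `var(a) = H ⊗ V_g`, and a permanent-environment vector
  `pe_l ∈ R³` per phenotyped animal with `var(p) = I ⊗ V_p`;
* residuals: independent, with one variance per 10-month age class
  (6 classes by default, configurable).

Ages are standardized as `x = 2t/60 − 1` and the basis is
`φ_k(x) = sqrt((2k+1)/2) P_k(x)`, the normalized (Kirkpatrick-style)
convention, orthonormal under the uniform weight on [−1, 1]. The same
`t_min=0, t_max=60` standardization is applied to fixed and random
regressions.

Identifiability: the first herd-year *and* the first birth-month level are
dropped and the constant covariate `φ_0` carries the datum. (Keeping the
birth-month block complete would be exactly collinear with `φ_0`.) GEBV
contrasts are invariant to this choice; the invariance is tested.

## 2. Single-step relationship matrices

* `A⁻¹` by Henderson's rules with Meuwissen–Luo inbreeding coefficients;
  `A` and `A22` by the tabular method (guarded at 20,000 animals — this
  package is deliberately desk-scale).
* `G = qZZ′` (VanRaden method 1) with `Z = M − 2p` and
  `q = 1/(2Σ p_o(1−p_o))`. Centering frequencies are the observed panel
  frequencies by default; supplied (base-population) frequencies are a
  config option. Note that with observed frequencies `G·1 = 0` exactly,
  so raw `G` is singular — tuning/blending is what makes it invertible.
* Tuning rescales `a + bG` so mean diagonal and mean off-diagonal match
  `A22` (a 2×2 linear solve); blending forms `(1−α)G + αA22`, α = 0.05.
  Default order is tune-then-blend (the convention of the standard
  evaluation toolchains); blend-then-tune is a switch because the two
  orders differ numerically.
* `H⁻¹ = A⁻¹ + [0 0; 0 G_adj⁻¹ − A22⁻¹]`, with dense Cholesky-based
  inversions of the genotyped-block matrices (raising if blending left a
  non-PD matrix).

## 3. Solving and prediction-error variances

The MME are assembled sparse, in animal-major coefficient order, with the
variance matrices entering inverted (`kron(H⁻¹, V_g⁻¹)`,
`kron(I, V_p⁻¹)`). The solver is conjugate gradients with a Jacobi
preconditioner; the convergence criterion is the squared norm ratio
`‖rhs − LHS·x‖² / ‖rhs‖² ≤ 1e−14` (the "squared ratio of the norm"
reading). For oracle comparisons the tests run the solver to ~1e−26,
i.e. numerical convergence.

`C²²`, the additive-coefficient block of `LHS⁻¹` restricted to genotyped
animals, is obtained from a sparse LU factorization with unit right-hand
sides — mathematically the same quantity large-scale software obtains by
sparse inversion, computed differently; a size guard (default 50,000
unknowns) refuses problems this strategy does not suit.

## 4. The GWAS step

For each requested age (default 10–60 by 10):

1. `GEBV_t = φ_t′ â_l` for genotyped animals;
2. `β̂_t = q W′ G_adj⁻¹ GEBV_t`;
3. `var(β̂_t) = diag[q²(1−α)² W′G_adj⁻¹(G_adj σ²_ut − C_t²²)G_adj⁻¹W]`
   with `σ²_ut = φ_t′V_gφ_t` and `C_t²²` the per-age collapse of `C²²`.
   Entries that are negative only by round-off are clipped to zero;
   negative beyond `1e−8` of scale raises (inconsistent inputs).
4. `p = 2(1 − Φ_N(|β̂/se|))`, with `−log₁₀p` evaluated through the normal
   log-survival function so that extreme signals do not underflow.
5. Variance explained: `100·2p_o(1−p_o)β̂²_ot / σ²_ut` percent.

The trailing factor of the variance expression is implemented as `G⁻¹W`:
the alternative literal reading `GW` is dimensionally impossible (see the
zero-information limit `C_t²² = Gσ²_ut`, where the variance must vanish).

Multiple testing uses the Li–Ji effective number of tests
`M_eff = Σ_i [I(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)]` over the eigenvalues of the
SNP correlation matrix, computed per chromosome and summed (the exact
full-matrix mode exists and is used as the oracle in tests; eigenvalues
are rounded at 1e−9 so perfect-LD blocks stay integral). The genome-wide
threshold is `−log₁₀[1 − (1 − α)^{1/M_eff}]`; at `M_eff = 8,876` and
α = 0.05 this is 5.24. SNPs significant at every requested age are
classified *persistent*, at some but not all ages *transient*, otherwise
*null*. When both `G` variants could be used in the back-solve, the
blended/tuned `G_adj` is used throughout for consistency.

## 5. Gibbs sampler for variance components

Variance components are estimated on the pedigree-only model (no genomic
information), as evaluation pipelines conventionally do. The sampler
alternates:

* **fixed effects**: one joint multivariate-normal draw (the X′R⁻¹X
  Cholesky is ~60-dimensional and cheap). Scalar-at-a-time updates are
  *not* used: a Gauss–Seidel cascade can park the overall mean in the
  herd-year dummies and leave one herd-year's animals to carry it in
  their random intercepts, after which the chain takes astronomically
  long to recover.
* **animal effects**: for each phenotyped animal, the pair `(u_l, pe_l)`
  is drawn as one joint 2k-dimensional block. This matters: the
  likelihood sees only `u_l + pe_l` (both multiply the same covariates),
  so separate updates random-walk along that ridge and the variance draws
  follow the walk instead of the data. Non-phenotyped animals get a
  k-dimensional draw from the pedigree-conditional prior. The sparse
  `A⁻¹` neighbor structure makes each sweep linear in records; the sweep
  is JIT-compiled with numba (a pure-Python fallback exists).
* **variances**: `V_g | a ~ IW(ν₀ + n_ped, S₀ + U′A⁻¹U)`,
  `V_p | pe ~ IW(ν₀ + n_phen, S₀ + P′P)`, and each residual class from a
  scaled inverse chi-square.

Priors default to inverse-Wishart with **identity** scale and
`df = k + 2`, and residual df 1 with scale 1 — proper and weak at the
sample sizes targeted. A scale matrix much smaller than the trait
variance (e.g. 0.01·I) is *not* weak: its `|V|^{−(k+2+1)/2}` factor pulls
`V_p` into a degenerate funnel the chain cannot leave. The location sweep
was validated exactly against the Gaussian full conditional
(mean = MME solution, covariance = LHS⁻¹) on a small instance.

Chain defaults are 20,000 iterations, 5,000 burn-in, thinning 10. The
test suite and the acceptance script use reduced chains (≈700–800
iterations); with the blocked sweep the chains reach the stationary
region within ~100 iterations at the tested sizes, and 5-seed posterior
means recover generating components within a few percent.

Derived quantities: `h²(t) = φ′V_gφ / (φ′V_gφ + φ′V_pφ + σ²_e(t))` and
`r_g(t₁,t₂) = φ₁′V_gφ₂ / sqrt(φ₁′V_gφ₁ · φ₂′V_gφ₂)`, reported on a
monthly grid.

## 6. The synthetic-data generator

The generator is the package's substitute for proprietary national data;
its defaults are a desk-scale version of such a dataset:

* **Pedigree**: founders with alternating sexes; each generation mates
  every dam once, with each sire serving `dams_per_sire = 4` dams
  (polygynous, dairy-like). This is a deliberate design decision: under
  strictly monogamous random mating each family contributes one
  phenotyped female and the likelihood surface for `V_g` vs `V_p` is
  nearly flat (verified by a REML profile scan) — paternal half-sib
  families are what make the additive/permanent-environment split
  identifiable, in the simulation exactly as in real dairy populations.
  `dams_per_sire = 1` restores monogamy. No selection, no deliberate
  inbreeding.
* **Genotypes**: gene dropping. Founder gametes are Bernoulli(p) draws
  with `p ~ U(0.05, 0.5)`; descendants inherit one random allele per
  parent per locus. Default is unlinked loci; an optional block mode
  (random phase, one crossover per chromosome) creates LD so the
  `M_eff < m` case is realistic. Per-locus transmission choices can be
  stored for replay tests. A uniform missing-rate knob exists solely to
  exercise the call-rate filter.
* **Effects**: `U = L_A Z L_{V_g}′` gives exact MVN(0, V_g ⊗ A) curves
  (truth precedes genotyping, so A rather than H); `pe ~ MVN(0, V_p)`
  i.i.d. for the phenotyped set (females by default). Injected QTL add
  `w_{lo}β_o` (centered dosage × coefficient vector) and the polygenic
  covariance is reduced by `Σ 2p(1−p)ββ′` so the total stays `V_g`
  (raising if the QTL demand more variance than `V_g` has).
* **Phenotypes**: herd-year and birth-month effects are drawn
  N(0, 2²) / N(0, 0.5²); the default mean curve rises concavely from
  ~87 to ~148 trait units across the age range; residual SDs fall with
  age (8 → 4), so heritability rises from ≈0.3 to ≈0.5 — the qualitative
  pattern reported for growth traits. Each animal receives 5–30 records
  (mean ≈ 17.5, matching the recorded-data regime) at uniformly sampled
  monthly ages; 90% of animals are forced to satisfy the data edits
  (≥3 records, one before 10 and one after 30 months) so the filters have
  work to do without emptying the data.

**What a green test does not establish**: the generator draws exactly the
covariance structure the model assumes. Green recovery tests therefore
validate the estimation machinery, not robustness to model misspecification
(non-Gaussian residuals, selection, genotyping error, age-measurement
error, heterogeneous herd variances are all absent by design).

## 7. Data edits

* Markers: call rate ≥ 0.90 first, then minor allele frequency ≥ 0.05 on
  the survivors; surviving missing dosages are mean-imputed (`2p_o`).
* Records: per integer age, values deviating more than 5 SD from the
  grand age-group mean are removed (groups with < 2 records are skipped
  with a warning — no SD is defined); then animals are kept only with
  ≥ 3 remaining records including one before 10 and one after 30 months.
  Outlier removal precedes eligibility; the grand (not herd-specific)
  age-group mean is used; fractional ages are floored to whole months.

## 8. Known limitations

* Desk scale by design: dense `A`/`A22` and LU-based `C²²` cap the
  problem size; no APY/Colleau-style large-scale machinery.
* No genotype imputation (mean imputation only), no metafounders or
  unknown-parent groups, no multi-trait models, no SNP-weighted
  (iterative) G.
* The Šidák-style threshold treats ages jointly only through `M_eff`
  over SNPs; no correction across the six age points is attempted, so a
  handful of single-age exceedances is expected under the null.
* Single-seed variance-component estimates at a few hundred phenotyped
  animals remain weakly identified along the `V_g`/`V_p` intercept ridge;
  recovery statements in the tests are 5-seed averages at ≈1,450
  phenotyped animals.
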