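# Methods

## Model

All Bayesian families share the weighted linear model
`y = μ1 + Xβ + e`, `e ~ N(0, D σe²)`. When the response is a
de-regressed proof (DRP) with per-record reliability `r²ᵢ`, the
residual weight is `d_ii = (1 − r²ᵢ)/r²ᵢ`, which down-weights records
whose DRP carries little information; for plain or pre-corrected
phenotypes `D = I`. The DRP reliability algebra is
`λ = (1 − h²)/h²`, `ERC = λ·REL/(1 − REL)` and
`r²_DRP = ERC/(ERC + λ)`.

Inverse-gamma notation is fixed package-wide as IG(shape, rate) with
density ∝ `x^(−shape−1) exp(−rate/x)`. The prior hierarchies, written
entirely in that convention:

* **BayesU (Horseshoe)** — `βₖ ~ N(0, λₖ²τ²)`,
  `λₖ² ~ IG(½, 1/νₖ)`, `νₖ ~ IG(½, 1)` (equivalently `λₖ ~ C⁺(0,1)`),
  flat prior on τ itself, so the τ² conditional carries a `(τ²)^(−½)`
  transform factor and is `IG((m−1)/2, ½Σβₖ²/λₖ²)` — proper only for
  m ≥ 2, and floored at 1e−12 when all effects vanish numerically.
* **BayesHP (Horseshoe+)** — one more half-Cauchy layer:
  `λₖ² ~ IG(½, 1/θₖ)`, `θₖ ~ IG(½, 1/ηₖ²)`, `ηₖ² ~ IG(½, 1/νₖ)`,
  `νₖ ~ IG(½, 1)`, and the global scale `τ² ~ IG(½, 1/ξ)`,
  `ξ ~ IG(½, N²)`, i.e. `τ ~ C⁺(0, 1/N)` with N the training size.
* **BayesHE (half-t, estimated df)** — `λₖ² ~ IG(υ/2, υ/θₖ)`,
  `θₖ ~ IG(½, 1)` (equivalently `λₖ ~ half-t(υ, 1)`), the same
  `C⁺(0, 1/N)` global scale, and `υ ~ Gamma(a, b)` with b a **rate**
  (prior means a/b = 4 and 5 for the two shipped settings a=4, a=5 with
  b=1). The second argument of the λₖ² layer is the rate `υ/θₖ`: that
  is the only reading consistent with the υ full conditional, whose
  data terms are `−(υ/2)Σ log(θₖλₖ²) − υΣ 1/(θₖλₖ²)`, and it is what
  the grid and quadrature oracles in the test suite verify.
* **BayesA/BayesB** — `βₖ = 0` with probability π (0.95 for BayesB, 0
  for BayesA), otherwise a scaled-t effect implemented via
  `σ²β,ₖ ~ inv-χ²(df, S²) = IG(df/2, df·S²/2)`.
* **GBLUP** — `y = μ1 + g + e`, `g ~ N(0, G σg²)` with the VanRaden
  relationship matrix `G = (M−P)(M−P)′ / 2Σpₖ(1−pₖ)`.

## Gibbs sampling

The update order per sweep is μ → marker loop (each βₖ with its local
scales) → global scales (τ², ξ) → υ (BayesHE, Metropolis–Hastings) →
σe². Marker effects are drawn from
`N((xₖ′W r)/σe² / c, 1/c)`, `c = xₖ′W xₖ/σe² + 1/vₖ` with `W = D⁻¹`
and `r` the residuals excluding marker k, updated incrementally in
O(n); residuals are refreshed from scratch every 1,000 sweeps (drift
without any refresh measures < 1e−8 over 10,000 sweeps). The BayesB
indicator is sampled *collapsed* — βₖ integrated out of the
marker-in/marker-out likelihood ratio analytically — which mixes far
better than joint proposals at m ≫ n and is checked against a
quadrature enumeration oracle.

Priors the model leaves open: flat on μ and Jeffreys (∝ 1/σe²) on σe²,
keeping both conditionals conjugate (`σe² | · ~ IG(n/2, ½Σeᵢ²/dᵢᵢ)`).
Genotype columns are centered by twice the training allele frequency
for all Bayesian families, matching the GRM construction; validation
animals are centered with training frequencies. DGVs exclude μ because
every reported metric (correlation, regression slope) is invariant to
that constant shift. The realized additive variance recorded in the
traces is `Vg = var(Xβ)` with denominator n−1.

The υ step is a random-walk proposal on ζ = log υ (υ is positive);
the ζ-space target includes the exp(ζ) Jacobian. The proposal sd
defaults to 0.5 and is adapted by Robbins–Monro toward 0.44 acceptance
during burn-in only, then frozen, preserving the stationary law. υ is
clamped to [0.05, 200] — Γ(υ/2) under/overflows far outside any
plausible df. Numerical guards elsewhere: all IG draws via
reciprocal-gamma with the rate clamped to ≥ 1e−300, and local
variances clamped to [1e−12, 1e12] (Horseshoe tails overflow double
precision without this).

Chain defaults are 50,000 sweeps, 20,000 burn-in, thinning 50 (600
saved draws); the `--fast` preset (5,000/2,000/10) is used throughout
the test suite and the acceptance script. Chains are a pure function
of the integer seed: all randomness flows through one numpy Generator,
with the compiled marker-loop kernels consuming pre-drawn variates.

## GBLUP details

The mixed-model equations are solved with the second block
premultiplied by σg²G, avoiding G⁻¹ — the GRM built from
data-frequency-centered codes always has the vector of ones in its
null space. Before any solve G is stabilized as 0.99·G + 0.01·I
(configurable). Variance components come from EM-REML: the model is
whitened by D^(−1/2) and the whitened GRM eigendecomposed once, making
every EM iteration O(n); the restricted likelihood is asserted
non-decreasing at every step, convergence is relative change < 1e−8
(components pinned at the zero boundary count as converged), and
non-convergence returns the last iterate with a warning. In
cross-validation the components are re-estimated per training fold by
default (switchable) so nothing leaks from the test fold. The
identity GBLUP ≡ SNP-BLUP at `σ²β = σg²/2Σpₖ(1−pₖ)` holds to < 1e−6
and is enforced in the tests.

## Synthetic data generator

The generator emulates a QTL-MAS-workshop-style design: 20 founder
sires × 10 dams each × 15 offspring per dam (3,000 offspring), five
chromosomes of 1,400 SNPs, 8 QTL, target heritability 0.3, and one
third of each family genotyped but not phenotyped. Founder linkage
disequilibrium comes from a latent Gaussian AR(1) per haplotype
(lag-one correlation `ld_decay`, default 0.9) thresholded at the
per-marker allele frequency (frequencies uniform on 0.1–0.9);
offspring are gene-dropped with Poisson(1) crossovers per chromosome.
QTL are additive biallelic with Gaussian (default) or signed-gamma
effects and optional pairwise epistatic product terms behind a flag —
the workshop's quadri-allelic, imprinted and phase-linked loci are
deliberately simplified to a controllable architecture. Residuals are
decorrelated from the genetic values and rescaled post hoc so the
*realized* (sample) heritability hits its target exactly, matching the
"realized heritability" convention rather than an expected-variance
calibration. DRP-like records add noise of variance
`var(gv)·(1−r²)/r²` per record.

What the simulator does **not** emulate: coalescent founder history,
sequence-level mutation, selection, or multi-generation pedigrees.
Passing tests on these data show the samplers and the harness are
correct and that the qualitative architecture response (shrinkage
models ≥ GBLUP on sparse traits, parity on dense ones) holds; they do
not certify accuracy levels on real livestock data.

## Validation strategy

* Every conjugate conditional (βₖ, μ, σe², λₖ², θₖ, ηₖ², νₖ, τ², ξ,
  σ²β,ₖ) is checked against a brute-force grid-integration oracle on
  fixed tiny states (sup CDF gap < 1e−3), and the compiled kernels are
  bound variate-for-variate to the same parameterizations.
* The half-Cauchy mixture identity (x² ~ IG(½,1/a), a ~ IG(½,1/A²) ⇒
  x ~ C⁺(0,A)) is verified by simulation for A = 1 and A = 1/N, and
  the composed Horseshoe+ local prior against its closed-form marginal
  density (4/π²)·log λ/(λ²−1).
* The υ step is validated three ways: exact Gamma(a,b) prior recovery
  at m = 0, agreement with a quadrature-normalized posterior mean on a
  frozen m = 50 state, and a detailed-balance flow check.
* A Geweke-style joint-distribution test runs each family two ways —
  prior draws vs Gibbs sweeps interleaved with data regeneration — and
  compares first and second moments. Because the shipped priors on μ,
  σe² and BayesU's τ are improper, the rig switches on proper options
  (μ ~ N(0,1), σe² ~ IG(4,3)) and holds BayesU's τ² fixed; and because
  τ under C⁺(0,1/N) has no finite moments, the rig compares moments of
  log τ² (and log σe²), which are finite for every family.

## Problem sizes and defaults chosen for the shipped studies

The acceptance computations use 1,000 individuals × 2,000 SNPs with a
single 5/6 train/test split and the fast chain preset — large enough
for the sparse-vs-dense architecture contrast to be unambiguous, small
enough for a desk run. QC thresholds default to MAF ≥ 0.01, HWE
χ²(1 df, no continuity correction) p ≥ 1e−6, call rate ≥ 0.90, applied
individuals-first with marker statistics recomputed on the survivors;
monomorphic markers are always dropped, and QC precedes mean
imputation (each missing call replaced by 2pₖ). BayesA/B leave the t
scale open; the default sets `S² = h²_prior·var(y)·(df−2)/(df·Σ2pₖ(1−pₖ))`
with df = 4.2 and h²_prior = 0.5, so the implied prior genetic
variance is half the phenotypic variance; both are configurable and
logged.

## Known limitations

Single trait, single chain, additive effects only; no pedigree
A-matrix or single-step H-matrix; no BayesCπ (estimated π) and no
regularized-horseshoe variants; convergence diagnostics beyond μ/Vg
traces (ESS, R̂) are left to external tooling such as arviz; DRP
construction from full pedigree EBV deregression is out of scope — the
simulator emits DRP-like records directly from true genetic values.
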