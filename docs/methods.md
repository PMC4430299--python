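# Methods

## Model

`hetmap` maps a three-allele, methylation-aware QTL that modulates the
transition dynamics of two interconverting cell subpopulations, using a
sample of n unrelated individuals from a random-mating population, each
with a SNP genotype and a bivariate longitudinal phenotype.

**Mean dynamics.** The expected subpopulation sizes solve either the
linear system

    dx1/dt = r x1 − k1 x1 + k2 x2
    dx2/dt = r x2 + k1 x1 − k2 x2

or a nonlinear variant adding feedback terms −k3 w2 x1 + k4 w1 x2 on
dx1/dt (mirror-signed on dx2/dt). The feedback weights w_i are taken to
be the subpopulation *proportions* x_i/(x1+x2): the tabulated feedback
rates (k3, k4 ≈ 0.5–0.7) are commensurate with the growth rate only if
the feedback terms are O(k·x), which the proportion convention delivers;
raw-size weights would make them O(k·x²) and dimensionally inconsistent
with the other rates. A `w_convention="size"` switch exposes the
alternative reading. In both models the transition/feedback terms cancel
in the sum, so x1+x2 grows exactly like e^{rt} — a structural invariant
the test suite checks to 1e-6.

**Genetics.** The QTL alleles are Q, q and the methylated epiallele q⁺
(frequencies q₁, q₂, 1−q₁−q₂), giving six genotypes indexed
j = 5..0 = QQ, Qq, Qq⁺, qq, qq⁺, q⁺q⁺. A biallelic marker (M/m,
frequency p) is linked to the QTL through disequilibria D₁ (M–Q) and D₂
(M–q), producing six haplotype frequencies (e.g. P_MQ = p·q₁ + D₁).
Under random union of haplotypes the 3×6 joint genotype table and the
QTL-given-marker conditional table follow by elementary expansion; both
are verified in tests against exhaustive enumeration of the 36 ordered
haplotype pairs. Parameter combinations that push any haplotype frequency
outside [0,1] raise an error rather than being projected back — silent
projection would corrupt simulation truth.

**Residuals.** Stacked residuals e(t) = (e1, e2)(t) at the T observation
times follow a bivariate first-order structured antedependence process,

    e(t) = Φ e(t−1) + ε(t),   Φ = [[a1, c1], [c2, a2]],   e(0) = 0,

with time-invariant bivariate-normal innovations (SDs ν₁, ν₂,
correlation ρ). The own-lag coefficients are a1, a2 and the cross-lags
c1 (variable 2 into 1) and c2 (1 into 2). Because the stacked residual
vector is a unit-determinant transform of the stacked innovations, the
2T×2T covariance has log-determinant T·log(ν₁²ν₂²(1−ρ²)) for *any* lag
coefficients. No stationarity is imposed — the bundled design values
include cross-lags above one, so the process is explosive but perfectly
well defined over the finite horizon; with such coefficients no
stationary initial distribution exists, which is the reason for the
e(0)=0 convention. The zero start also yields the clean determinant
formula.

**Likelihood.** Y_i = (x1(1..T), x2(1..T)) is a six-component
multivariate-normal mixture with weights π(j | m_i) and genotype means
from the ODE solutions. All density work is in log space with
log-sum-exp; the covariance is factorized once per evaluation and shared
across individuals.

## Estimation

A generalized EM:

1. **E-step** — posterior genotype probabilities per individual.
2. **Haplotype M-step** — closed-form expected haplotype counting, with
   the double-heterozygote phase split by weights θ recomputed from the
   current frequencies (that recomputation *is* the E-step over phase, so
   this update is the exact M-step of an EM on the joint
   (marker, phenotype) model and ascent is guaranteed).
3. **Θ blocks** — for each genotype, Nelder–Mead on the posterior-
   weighted mean trajectory in the Mahalanobis metric of the current
   covariance (sufficient for the complete-data objective). Means are
   evaluated by classical fixed-step RK4; for the linear model RK4
   reduces algebraically to powers of the one-step matrix
   I + hA + … + (hA)⁴/24, which is how it is computed (validated against
   naive stepping at 1e-12).
4. **Ψ block** — Nelder–Mead on n·logdet Σ + tr(Σ⁻¹S) with S the pooled
   posterior-weighted scatter (independent of n per evaluation).

Every block is warm-started at the current value, so a sweep cannot
decrease the complete-data objective; the *joint* log-likelihood is the
tracked ascent objective and is asserted non-decreasing in the test
suite. The conditional mixture log-likelihood (the quantity used in
likelihood-ratio tests) is reported alongside. Rates and innovation SDs
are optimized on the log scale, the innovation correlation through
atanh, so parameter invariants hold by construction. Convergence is a
relative joint-loglik change below `em_tol` (default 1e-6), with a
default cap of 500 sweeps and Nelder–Mead budgets of 80 evaluations per
block per sweep — limited per-sweep budgets make the scheme a
progressive-refinement generalized EM rather than an exact ECM, which is
both faster and still monotone.

### Identifiability and label handling

Two genuine identifiability features of this design shape the estimator:

* **Allele-gauge invariance.** The likelihood is *exactly* invariant
  under relabelling the three QTL alleles: any permutation of (Q, q, q⁺)
  permutes genotype classes and haplotype frequencies consistently and
  reproduces the same distribution. Fits are therefore reported in a
  canonical gauge: allele "q" is the most frequent, "Q" second, "q⁺"
  rarest (matching the bundled designs' 0.5/0.4/0.1).
* **Near-tied labelings under weak LD.** With the design's D₁=0.01,
  D₂=0.02, the marker distribution of the Qq⁺ class is nearly identical
  to that of the qq⁺ class (and QQ's to qq's). Swapping those labels
  changes the log-likelihood by an amount comparable to sampling noise,
  so a cold-started maximum-likelihood fit lands in either labelling
  depending on the realized data.

The cold-start protocol therefore combines: a deterministic data-driven
**cluster start** (per-column robust scaling by median sorted-neighbour
differences — a within-class noise estimate that does not require knowing
the classes — farthest-point seeding so rare genotype classes are not
swallowed, a few Lloyd iterations, one ODE curve fit per cluster, and
cluster→label assignment by a marker-composition score); an exact-null
start (all genotypes at the single-curve fit, which guarantees the full
model ascends from the null log-likelihood and keeps LR statistics
non-negative); an improvement-gated **relabel search** over all 720
genotype permutations inside EM; and a post-fit **swap polish** that
restarts EM briefly from the top-scoring pairwise label transpositions.
All of it is deterministic given the seed.

The **replicate study** (`replicate_study`) warm-starts each replicate's
EM at the generating values and disables the relabel machinery
(`start_at_truth=True`, the default). This measures the estimator's
dispersion around the truth-anchored likelihood mode — the standard
protocol for simulation studies of mixture estimators, and the only one
whose per-genotype summaries are meaningful given the near-tied
labelings above. Replicate datasets are redrawn until every genotype
class is non-empty (the rarest class, q⁺q⁺ at frequency 0.01, is empty
in ~13% of n=200 draws, and its parameters are undefined on such a
draw). `start_at_truth=False` switches to the cold protocol.

### Hypothesis tests

QTL existence: LR = −2(logL₀ − logL₁) against the single-curve null,
with an empirical threshold from permuting each individual's marker code
against the intact phenotype vector (preserving the longitudinal
covariance under the null). Every full fit inside the permutation loop —
including the observed one — starts from the same marker-independent
null fit with identical optimizer settings, so the observed statistic is
exchangeable with the permuted ones and the p-value
(1 + #{LR_perm ≥ LR_obs})/(n_perm + 1) is exactly calibrated at any
permutation count. (Warm-starting permuted fits from the *observed* fit,
while the observed fit gets a richer search, would break exchangeability
and be anticonservative — hence this design.) Pleiotropy and other
reduced models are expressed through `ConstraintSpec` equality patterns
over genotype ODE parameters.

Additive/dominance effect trajectories use the classical biallelic
contrasts applied pairwise to the three alleles: for pair (A, B),
a(t) = (μ_AA − μ_BB)/2 and d(t) = μ_AB − (μ_AA + μ_BB)/2, per variable.
A three-allele decomposition is not uniquely defined; outputs are
labelled by allele pair.

## Synthetic data

The generator draws each individual's (marker, QTL) genotype by random
union of two haplotypes, evaluates the genotype's ODE mean trajectory,
and adds one SAD(1) residual path. The bundled registry holds the twelve
study configurations ({linear, nonlinear} × n∈{200,400} × heritability
label ∈ {0.05, 0.1, 0.2}) with genetic parameters
(p=0.6, q₁=0.4, q₂=0.5, D₁=0.01, D₂=0.02), six genotype-specific ODE
parameter sets per model family, and per-label SAD(1) sets. The
heritability labels are nominal: the residual parameter sets are used
verbatim and the realized variance-ratio heritability is reported, not
enforced (with the bundled explosive lag coefficients the early-time
noise is tiny while genotype curves separate strongly, so realized
values are well above the labels); `calibrate_residual_scale` bisects a
multiplier on (ν₁, ν₂) for users who need an exact value. Heritability
itself is defined as σ²_g/(σ²_g+σ²_e) at a reference time (default: the
last observation), with σ²_g the genotype-frequency-weighted variance of
the six mean curves and σ²_e the SAD(1) marginal variance there.

What the generator does *not* emulate: genotyping error, missing
observations, between-individual variation in initial state or sampling
times, multi-locus architecture, and non-Gaussian measurement noise.
Passing tests therefore demonstrate correctness of the algebra and the
estimator under the stated model, not robustness of the method on real
cytometry time courses.

## Numerical choices and problem sizes

* Time grid: t₀=0, observations at t=1..9 (T=9), RK4 substep h=0.05;
  initial state (1, 1) shared by all genotypes and known to the fitter.
  The nine-point grid spans a 21-day, roughly 2–3-day-interval culture
  design; estimating initial conditions is out of scope.
* Sub-seeds: replicate k derives (simulation, fitting) seeds from a
  counter-based `SeedSequence([seed, k])` split, so replicate sets are
  reproducible and extensible; all randomness flows from explicit seeds.
* Degenerate inputs: haplotype frequencies that leave the simplex,
  non-positive innovation SDs, |ρ|≥1, zero marker-class frequencies,
  0/0 phase weights, and non-finite ODE states all raise named errors.
* The bundled checks run at scaled-down sizes chosen to keep the whole
  suite fast while leaving the conclusions unchanged: 20 replicates per
  recovery scenario in the test suite and 30 in the reproduction script
  (the original design used 100), a 20-dataset × 39
  permutation calibration smoke test (exact calibration holds at any
  permutation count with (n_perm+1)·α integral), and 10⁵ Monte-Carlo
  paths for the covariance check.

## Known limitations

* Single marker, single QTL; no genome-wide scan or multiplicity control
  beyond the permutation threshold.
* Standard errors are across-replicate dispersions only; no analytic
  information matrix.
* The pairwise additive/dominance decomposition is one defensible
  convention for a three-allele locus, not canonical.
* With weak marker–QTL LD the labelling of heterozygote classes carrying
  the rare epiallele is close to non-identifiable (see above); on real
  data, reported per-genotype parameters for those classes should be
  read with that caveat.
* k1 and k2 are separately well identified only when the transition flux
  is appreciable over the observation window; for slow-transition
  genotypes the fit constrains mainly their net effect.
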