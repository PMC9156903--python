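# Methods

## Model

A haploid population of constant size N sits at mutation–selection–drift
balance for a biallelic locus until an instantaneous environmental
change at t = 0.  Before the change the focal ("survival") allele has
fitness 1 − s_d relative to the wild type and mutation between the
alleles is symmetric at rate μ per individual per generation; after the
change the wild type declines at rate δ per generation while the
survival allele grows at net rate s_r = s_b − δ > 0.

Survival of the population is governed by the number of allele copies,
not its frequency: each of the A_st = pN standing copies, and each of
the A_dn = (1 − p)Nμ/δ copies expected from mutation during the
decline, independently founds a surviving lineage with the
branching-process establishment probability π(s_r) (Poisson offspring;
the larger root of π = 1 − e^{−(1+s)π}).  The (1 − p) factor in A_dn
extends the classical rescue expression to initial frequencies that are
not small, which matters here because drift makes high p common in
small populations.

The initial frequency follows Wright's stationary density
φ(p) ∝ e^{−γp} (p(1−p))^{α−1} with α = 2Nμ and γ = 2Ns_d.  Averaging
the conditional survival probability over φ gives the closed form

    P_survival = 1 − e^{−Nπμ/δ} · ₁F₁(α, 2α, −2Ns̃) / ₁F₁(α, 2α, −γ),
    s̃ = s_d + (1 − μ/δ) π(s_r)/2,

which the package evaluates directly, alongside an independent
quadrature of the integrand against φ used as a cross-check (the two
agree to better than 1e−6 across all tested parameter sets).

Assumptions worth keeping in mind: haploid, single locus, symmetric
mutation; the population is at Wright's equilibrium at the change
(reached only on a 1/μ timescale — a strong assumption for real
populations); survival lineages reproduce independently except in the
Ricker variant; N is treated as continuous in the analytic expressions
(the closed form is smooth in N) and as an integer count in the
simulators.

## Parameters

| symbol | meaning | default |
| --- | --- | --- |
| s_b | benefit of the survival allele after the change (per generation) | 0.05 |
| δ | wild-type decline rate after the change | 0.01 |
| s_d | cost of the survival allele before the change | 0.001 |
| μ | symmetric mutation rate (per individual per generation) | 1e−5 |
| threshold | survival-lineage count declaring establishment | 2000 |
| r | Ricker intrinsic growth rate | 1.0 |

Two derived scales organize the results: N_neut = 1/s_d (below it the
cost is drift-dominated) and N_mut = 1/μ (above it a new copy appears
every generation and survival is essentially certain).  The survival
minimum exists when N_neut ≪ N_mut but the allele is not so deleterious
that survival is negligible at N_neut: with the defaults the rightmost
local minimum sits at N ≈ 1.2×10³.  The defaults for δ-, μ- and
s_d-sweeps reproduce that landscape; the benefit must be raised to
s_b ≈ 2 (establishment probability near one) before the dip disappears
entirely, while near-neutral cost (s_d = 1e−4 over N ≤ 1e4) or high
mutation supply (μ ≥ 1e−4) also restore monotone growth.

## Numerics

- **π(s)**: bisection on −expm1(−(1+s)x) − x over [1e−12, 1] to
  1e−13; expm1 keeps the bracket sign reliable when s is tiny.  π = 0
  for s ≤ 0.
- **₁F₁ in log space**: negative arguments are always routed through
  the Kummer transform ₁F₁(a,b,z) = e^z ₁F₁(b−a,b,−z) so the series
  has only positive terms.  scipy evaluates the transformed function up
  to z = 600; beyond that the series is summed directly in log space
  (cumulative log-term increments + logsumexp, immune to overflow,
  machine-precision accurate up to the z ≈ 4×10⁴ reached at N = 10⁶),
  with mpmath arbitrary precision as a final fallback.  Failures raise
  with the offending arguments rather than returning garbage.
- **Endpoint singularities**: for α < 1 the density diverges as
  p^{α−1} at 0 and (1−p)^{α−1} at 1.  All integrals against φ use
  QUADPACK's algebraic-weight (Gauss–Jacobi-type, QAWS) adaptive rule
  with the singular factors moved into the weight.  The test-suite
  oracles use a different route — the exact substitution p = t^{1/α} —
  so the two cannot share a failure mode.
- **Discretization for simulation**: the initial frequency is drawn
  from bin masses of φ on {0, 1/N, …, 1} (edge bins of width 0.5/N,
  interior bins centred on j/N).  Edge bins use the weighted rule
  above; interior bins use 20-point Gauss–Legendre per bin, vectorized,
  which is ample away from the endpoints.  Masses are renormalized to
  sum exactly to one (they already sum to 1 within 1e−10).
- **Vulnerable-N finder**: 200-point log-spaced scan of the closed
  form, keeping interior grid minima whose depth below the flanking
  local maxima is ≥ 1e−6 — saturated stretches where P ≡ 1.0 in double
  precision otherwise produce spurious flat "minima" — then
  golden-section refinement of the rightmost one in log N.
- **Degenerate inputs**: p ∈ {0, 1} is rejected by the log-density
  (divergent); conditioning mass below 1e−12 in the restricted survival
  raises; replicates hitting the generation cap are reported censored
  and excluded from survival fractions rather than misclassified.

## Simulators

The branching simulator draws wild-type and survival-lineage offspring
as Poisson with means (1−δ)L and (1−δ+s_b)M, then applies symmetric
mutation by binomial thinning in both directions — distributionally
identical to per-offspring flips but O(1) per generation.  A replicate
ends at extinction (L+M = 0) or establishment (M ≥ threshold, default
2000; doubling it changes estimates by less than sampling error).  One
root generator spawns an independent sub-stream per replicate, so
estimates are reproducible and order-independent.

The Ricker variant replaces unbounded branching with density
regulation: per-capita mean offspring exp(r[1 − N_t/K_t]) for the wild
type, whose capacity decays as K_t = K_0(1−δ)^t, and
exp(r[1 − N_t/K_0]) for survival-allele carriers.  The establishment
criterion is min(threshold, ⌈K_0/2⌉): a lineage at half of an
undiminished carrying capacity is established for all practical
purposes even when K_0 < 2000.  Note that the allele's selective
advantage here is emergent and time-varying — it is ≈ 0 at t = 0 (both
capacities equal) and grows toward e^r − 1 as K_t collapses.  With the
default r = 1.0 that late advantage is large and survival versus K_0 is
monotone; the non-monotonic landscape persists under density regulation
for modest growth rates (r ≈ 0.1, where the maximal advantage is
comparable to s_b), which is the regime the test suite exercises.  r
and the criterion are visible configuration, not hidden constants.

## What the simulations do and do not show

The simulators validate the analytic machinery under the model's own
assumptions (equilibrium initial condition, constant rates, single
locus).  Agreement between points and curves therefore checks the
mathematics and the code, not the biology: real populations may not be
at Wright's equilibrium, selection coefficients fluctuate, and linked
or multilocus variation is ignored.  Desk-scale problem sizes are used
throughout the suite — 10³ replicates per Monte-Carlo point (binomial
SE ≈ 0.016), 5×10³ for the worked extinction example, N up to 10⁶ in
closed form but up to 10⁴ in replicate sweeps; these sizes were chosen
so the full suite completes in minutes while keeping every comparison
inside 3 standard errors of its target.

## Known limitations

- Asymmetric mutation (u ≠ v), diploidy, multilocus genetics and
  structured populations are out of scope.
- The standing/de-novo composition P_total = P_stand + (1−P_stand)P_de novo
  is not algebraically identical to the closed-form marginal (the
  standing route ignores the (1−p) de novo weighting); at the defaults
  they differ by < 0.01 and both are reported, neither forced equal.
- The restricted ("rescue-only") survival renormalizes φ on p < p_max;
  truncation without renormalization would be an alternative reading.
- Wright's density is a diffusion approximation, least accurate at very
  small N, where the discretized bins inherit the same error.
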