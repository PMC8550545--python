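# Methods

This note records the statistical machinery, the numerical choices, and the
limits of what the package's tests demonstrate.

## Model check

The check deliberately does not use the analysis prior: the constraint is a
statement about the sampling model, so it is assessed under the uniform
(Dirichlet(1,…,1)) prior on the full simplex, for which the posterior given
counts T is Dirichlet(T+1).

**Positive-measure path.** `check_positive_measure` estimates prior and
posterior contents of Θ by Monte Carlo membership (the prior content uses
the closed form when the region has one: `a√(1−2a)π` for the trine ellipse
in (θ₁, θ₂) coordinates, where the uniform density is 2 and the ellipse
area is π/√det C; `1/(k+1)!` for the ordered cone by exchangeability).
RB = posterior/prior content, strength = posterior content (the binary-case
convention; for the ordered fly example this is what makes a huge RB with
posterior content 0.04 "weak evidence in favor").

**Distance path.** For measure-zero (or tiny) regions the prior and
posterior distributions of d(θ) = inf KL(θ‖θ*) are compared on bins
[0, δ), [δ, 2δ), …, anchored at 0, width exactly δ, no smoothing. RB_d is
the first-bin ratio; the strength is the posterior mass of the bins whose
bin-RB is ≤ the first bin's. Bins with zero prior mass but positive
posterior mass have infinite bin-RB and are excluded from that union; the
far tail beyond 10^5 bins is merged into one bin (it carries negligible
mass). δ is a practical-equivalence cutoff: if all relative cell-probability
errors are within δ, then log(p_ij/θ_ij) ≈ (p_ij−θ_ij)/θ_ij and the KL
distance is within ≈ δ as well — hence defaults δ = 0.01 (1 % relative
error, HWE) and δ = 0.02 (Zipf–Mandelbrot).

**Distances.**

* *HWE (any number of alleles l):* the minimizing allele frequency is the
  plug-in ω_i = θ_ii + ½ Σ_{j≠i} θ_ij. This is exact, not an approximation:
  the ω-dependent part of KL(θ‖HWE(ω)) is −Σ m_i log ω_i with
  m_i the expected allele frequencies, and the simplex-constrained maximizer
  of Σ m_i log ω_i is ω ∝ m. A numerical-minimizer cross-check is kept in
  the tests.
* *Ordered cone:* the KL projection is the pool-adjacent-violators fit
  (sklearn's `IsotonicRegression`): minimizing −Σ θ_i log q_i over
  nonincreasing simplex q forces q constant on pooled blocks at the block
  mean of θ. Cross-checked against an SLSQP solver.
* *Zipf–Mandelbrot:* d(θ) is minimized over a table of family members,
  β ∈ [0, 6] in steps of 0.02 and, per β, a log-spaced α grid ascending from
  −0.99 until KL(ZM(α,β) ‖ uniform) < δ/10 — large α approaches uniformity,
  so nothing further up contributes; β = 0 is stored once (every α is then
  uniform). The distance is a single matrix product
  (−H(θ) − max_g θ·log pmf_g), chunked for memory.
* *Equality-constrained quantum regions (cross-hairs, Pauli):* distance is
  minimized over the affine slice parameterized by the free coordinate of
  each constrained pair, with the quadratic ball constraint, via SLSQP from
  several starts. The tetrahedron (full-dimensional) optimizes over the
  whole simplex.

**Verdicts.** RB within one Monte Carlo standard error of 1 is reported
`neutral` rather than forced to a side. The error-probability routine
conditions "d(θ) = d₀" as d(θ) ∈ [d₀, d₀ + band) with band = δ/2 by default
— an approximation to the measure-zero conditioning, reported as such.

## Prior check

The conflict statistic is the prior-predictive tail probability of the
counts; ties on log m_T are included at tolerance 1e-12, all arithmetic in
log space (log-Beta via log-gamma). The reported flag uses the conventional
0.05 cutoff, configurable; the tail probability itself is the measure of
surprise, not a binary verdict.

* *Closed forms.* For a Dirichlet prior on θ, m_T is Dirichlet-multinomial.
  For a Dirichlet prior on allele frequencies under HWE, substituting
  θ_ii = ω_i², θ_ij = 2ω_iω_j makes the integrand a polynomial in ω:
  m_T(t) = multinom(n;t) · 2^{Σ_{i<j} t_ij} · B(α+e)/B(α) with allele
  exponents e_i = 2t_ii + Σ_{j≠i} t_ij. Normalization is verified by brute
  enumeration in the tests.
* *Importance sampling.* Where m_T has no closed form the integral is
  estimated by averaging L(θ)π(θ)/q(θ) over proposal draws (the
  "constant-aware" ratio estimator). The self-normalized variant was
  rejected: with a concentrated proposal and a flat target the plain prior
  weights π/q have enormous variance, while the integrand ratio Lπ/q is
  stable because the proposal tracks the likelihood. Effective sample size
  of the integrand weights is reported; below 1 % of the draws a warning is
  raised.
* *Trine prior.* The qubit Hilbert–Schmidt prior induces
  π(θ) ∝ (1 − Q(θ))^{1/2} on the trine ellipse (Q the quadratic form); its
  normalizer is (2π/3)·det(C)^{−1/2}, so the trine m_T values are fully
  normalized. The generator uses the polar map θ = c + S√r(cos ω, sin ω)
  with SᵗCS = I (the root of C⁻¹ — the root of C itself would not make the
  quadratic form of a draw equal r), ω ~ U(0, 2π), r ~ beta(3/2, 3/2).
  *Caveat:* this radial law and the density above are mutually inconsistent
  — pushing beta(3/2, 3/2) through the polar map actually gives a density
  ∝ Q^{1/2}(1−Q)^{1/2}, while the (1−Q)^{1/2} marginal corresponds to
  r ~ beta(1, 3/2). The package keeps the prescribed pair (sampler
  beta(3/2, 3/2) for the outer predictive draws, density (1−Q)^{1/2} inside
  m_T), which is the combination that reproduces the reference tail
  probabilities (≈ 0.87 symmetric, ≈ 0.15 asymmetric) and satisfies
  E[Q] = 1/2; the two self-consistent pairs give ≈ 0.73/0.08 and
  ≈ 0.29/0.32 instead. The proposal for each m_T evaluation is
  Dirichlet(t+1).
* *Ordered-cone prior.* ω ~ Dirichlet(α), θ = A_k ω. m_T is estimated in
  ω-space with a Dirichlet proposal whose mode is the observed frequency
  vector pulled back (by bisection along the segment to the prior mode) to
  the boundary of the cone, so proposal draws stay in the support, and
  whose concentration is tuned per evaluation: the log-IS estimate is
  biased downward when the proposal mixes poorly (Jensen), so each
  evaluation is run at a small concentration grid (default 20, 60, 180) and
  the largest estimate kept — the "smaller and larger values both give
  smaller estimates" heuristic, applied per evaluation.
* *Grouping.* When n is small relative to the dimension, most predictive
  frequency vectors fall outside the cone and the importance sampler
  degrades. `grouped_conflict_check` reduces the dimension by stride
  grouping (group j = cells j, j+m, j+2m, …), which preserves the ordering
  of the group sums. The grouped prior keeps the elicited concentration τ
  from the full problem and regroups the mode (spacing g·ε); the implied
  interval for the grouped problem — upper bound widened by the cell
  ceilings θ_i ≤ 1/i of the extra members, lower bound g·l — is reported as
  a diagnostic, along with p_m, the fraction of full-prior-predictive
  frequency vectors whose grouped version is in the cone (the quantity used
  to decide how far to group).

The tail probability converges, as n grows, to the prior probability that
the prior density is below its value at the true θ; the package exercises
this empirically (`conflict_convergence_experiment`) with the closed-form
Dirichlet predictive — the theory's regularity conditions (bounded,
a.s.-continuous density with null level sets) are not verified by code.

## Elicitation

Mode/concentration form α = 1 + τξ keeps every α_i ≥ 1 (no boundary
singularities). The smallest τ meeting coverage γ (default 0.99, "virtually
certain") is found by doubling from τ = 0.05 to bracket, then bisection to
0.1 % relative precision; the coverage curve is monotone in τ and Monte
Carlo coverage (10^5 draws per τ, needed when no Beta-CDF closed form
applies) uses a fixed seed across τ values so the search never oscillates.
Two-allele problems use the exact Beta CDF. The subsimplex
{ω : ω_i ≥ a_i} defined by lower bounds has equal edges, so its centroid —
the prior mode — is a_i + (1 − Σa_j)/l. Reference values: bounds (0.1, 0.5)
at γ = 0.99 give τ = 34.40 (quoted as 34.5, i.e. beta(11.35, 25.15), after
rounding); (0.01, 0.7) give τ = 52.8 (quoted 53); the ordered fly problem
gives τ ≈ 2.85 (flat mode) and ≈ 16.5 (maximal spacing).

For ordered probabilities, an equispaced nonincreasing mode
θ*_i = θ*_1 − (i−1)ε is feasible iff 0 ≤ ε ≤ 2/(k(k+1)), with ω-space mode
ξ_i = iε, ξ_{k+1} = 1 − k(k+1)ε/2; coverage for Eq.-style interval beliefs
uses θ₁ = Σ ω_i/i and θ_{k+1} = ω_{k+1}/(k+1).

## Synthetic data and what the tests show

`simulate_counts` implements the generate-θ-then-counts scheme: θ fixed, or
drawn from a prior sampler, then t ~ multinomial(n, θ). All simulated
studies in the tests use the sample sizes of the packaged datasets
(n = 7076 / 6756 trine, 212 CCR-5, 363 fly) and the Monte Carlo sizes
stated in each routine's defaults or the test body; the acceptance script
uses 10^6 distance draws (HWE), 10^5 content draws (trine/ordered) and 10^4
outer predictive draws (conflict), sizes at which the reference values
reproduce within a few Monte Carlo standard errors in seconds.

The generator draws i.i.d. multinomial counts exactly; it does not emulate
overdispersion, correlated sampling, detector drift or genotyping error.
Passing checks therefore demonstrate correctness of the inferential
machinery under the i.i.d. multinomial assumption, not robustness of the
checks to violations of it (the i.i.d. assumption itself is untestable from
T alone).

## Numerical choices

* Natural log throughout KL and m_T.
* Simplex construction tolerance 1e-12; inputs off by ≤ 1e-9 renormalized,
  anything worse rejected. Monotonicity tolerance 1e-10 (cone membership
  and the inverse bijection, which clips tiny negative ω).
* Infinite KL values (support violations) are represented as `inf`, never
  clipped; distance-table minimizers skip them naturally via `max` over log
  pmfs.
* Membership-by-distance tolerance 1e-10.
* RNG: numpy `default_rng`; every stochastic routine takes an int seed or a
  Generator; no seed means OS entropy (reports record the seed passed).
  Child seeds for independent sub-simulations come from `SeedSequence` and
  stay below 2³¹.

## Known limitations

* Trine distance and the equality-constrained quantum distances use local
  optimization (multi-start SLSQP); they serve diagnostics, not the hot
  Monte Carlo paths, and could in principle return local minima.
* The Zipf–Mandelbrot distance is a grid minimum: it upper-bounds the true
  infimum by the grid resolution; the zeta-function approximation for large
  k is not implemented.
* The Jensen-bias correction for the ordered-model importance sampler is a
  heuristic maximization over a small concentration grid, not a debiased
  estimator; tails computed through it are soft to ±0.05–0.1.
* `evidence_error_probabilities` rejects into a distance band; for very
  small bands the acceptance rate collapses (it raises with guidance).
* Dimensions beyond a few dozen cells are untested territory for the
  default Monte Carlo sizes; group first.
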