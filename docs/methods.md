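# Methods

## Observation models

**Behavioural arena scans.** Each trial runs three groups of five mated
females — one per cue treatment (reliable, unreliable, none) — through five
10-minute arena exposures ("runs"), with the count of females on the
uninfested-seed patch recorded at 20 scans per run (30-second bins; the bin
count is inferred from the totals, 66,000 observations = 660 females x 5
runs x 20 scans). The count is binomial in the group size with a
logit-linear predictor: degree-2 polynomials in scan time and run, cue
treatment and its interactions with both, line identity, and — in the
inbreeding experiment — cross type (inbred/outbred) with treatment and run
interactions. Trial identity enters as a Gaussian random intercept crossed
with treatment; because every trial contains all three treatments, the
crossing is implemented as two scalar variance components, trial and
trial-by-treatment cell.

One bookkeeping choice is not derivable from the reported test degrees of
freedom alone: with quadratic time and run, treatment x run and
treatment x time interactions each carry 4 df, but a full three-way product
would carry 8. The canonical specification here uses
treatment x linear(run) x quadratic(time) for the three-way term (4 df),
which reproduces the 4-df bookkeeping of both reported interaction tests
while keeping the quadratic saturation-in-time shape.

**Egg placement.** Per group and run, egg counts on uninfested and on
infested seeds are independent Poisson with log-linear rates (treatment,
run trend, inbreeding effects, shared trial intercept). Egg trials are one
group of five in a single treatment (96 trials = 480 females); treatments
advance across trials in blocks equal to the number of lines so that lines
and treatments stay crossed. Counts are capped at a configurable 20 eggs
per female (generator convenience against unrealistic Poisson tails).

**Larval survival.** Sixty female duos (3 lines x 2 cross types x 5
pre-infestation levels x 2 blocks) share 2,450 mung beans, split as evenly
as possible. Each bean draws a focal egg count concentrated on one egg
(three rare; the tail beyond three is calibrated so about seven beans per
experiment exceed it), and emergence is binomial with logit-linear
predictor in inbreeding, the competition experienced by a focal egg
(C = all eggs on its seed minus one, so singletons have C = 0 and the
admissible maximum is C = 6), their interaction, and a duo intercept.
Data preparation discards beans with more than three focal eggs (they are
rare and unevenly distributed across cross types) and beans that received
no focal eggs; every removal is counted in the filter log.

**Fecundity.** Hatched-egg counts per female are negative binomial with
cross-specific means; inbred-line means sit a configurable proportion
(default 0.575) below the outcrossed means.

## Generator calibration

Defaults are calibration values, not fitted estimates. They reproduce the
qualitative structure of the system — reliable > none > unreliable care,
learning across runs, inbred deficits that shrink with experience — and the
reported effect magnitudes: the survival defaults (logit intercept 1.9,
inbred −1.1, competition −0.35, interaction −0.25) imply a viability cost
of inbreeding of ≈0.21 at C = 0 and ≈0.87 at C = 6; the egg defaults imply
genome-wide selection of ≈0.37 (reliable), ≈0.49 (unreliable) and ≈0.52
(no cue). Baseline egg rates (e^2.3 ≈ 10 uninfested-seed eggs per group-run)
are on the scale typical of this genus. What the generator does **not**
emulate: spatial arena dynamics (behaviour is generated directly at the
observation-model level), within-group dependence beyond the shared
intercepts, female identity across runs, observer effects, and competitor
emergence. Passing tests therefore demonstrate that the inference chain
recovers known truth under the assumed observation models, not that those
models exhaust real arena data.

## Marginal likelihood and fitting

Random intercepts are integrated by adaptive Gauss–Hermite quadrature:
per group the integrand is re-centred at its conditional mode (found by
damped Newton; the penalized log-likelihood is concave for canonical
binomial/Poisson links) and re-scaled by the curvature there. One node is
the Laplace approximation; the default 15 nodes agree with brute-force
trapezoid integration to well below 1e-6 on small fixtures. A variance of
exactly zero removes the factor and recovers the ordinary GLM likelihood.

With several scalar factors the likelihood is approximated factor by
factor under conditional independence: the joint conditional mode of all
random effects is found by coordinate ascent, each factor is integrated
with the others held at their modes, and the observation likelihood is
counted once (loglik ≈ Σ_f AGQ_f − (F−1)·loglik at the modes). This is
exact for one factor and exact in the GLM limit. Its known cost: the
variance *split* between nested factors (trial vs trial-by-treatment) is
weakly identified and one component may sit at the floor; fixed-effect
estimates and likelihood-ratio tests are unaffected in recovery checks at
the full design size.

Fitting maximizes the marginal likelihood over coefficients and
log-variances (floor 1e-8) with L-BFGS-B from a statsmodels GLM warm
start, using an analytic score that holds the adaptive centring fixed
(error at quadrature-accuracy level). Convergence is declared when the
largest score component is below 1e-4 per observation — the relative
analogue of a gradient-norm criterion, chosen because an absolute
threshold is meaningless across four orders of magnitude of |loglik|.
The observed-information covariance comes from central differences of the
score; quasi-separation is flagged when any column's contribution to the
linear predictor exceeds 15 logits. Likelihood-ratio statistics are
2·Δloglik clamped at zero with df equal to the fixed-parameter difference;
drop-one tests against the full model are the default testing scheme.

## Posterior sampling

A Metropolis-within-Gibbs sampler mirrors the frequentist models: one
random-walk Metropolis block for the fixed effects (proposal shaped by the
GLM covariance), vectorized per-group random-walk updates for each factor's
latent intercepts (groups are conditionally independent), and conjugate
inverse-gamma draws for each variance component. Priors default to
Normal(0, 100) on coefficients and InverseGamma(0.001, 0.001) on variances
— an interpretation of "flat and weak" — and are configurable. Proposal
scales adapt toward acceptance 0.25 (blocks) / 0.44 (scalars) during
burn-in only and are frozen afterwards, preserving detailed balance for
the stored chain; the frozen scales are exposed so tests can assert it.
The default schedule stores every 100th of 100,000 post-burn-in iterations
(1,000 draws). Posterior summaries are means, medians and equal-tail 95%
intervals; derived quantities use the posterior mean as the point estimate
(mean vs mode is not fixed by convention here). An optional multi-chain
mode reports split-R̂.

## Selection quantities

All transformations are applied draw by draw and summarized afterwards.
Viabilities are population-level inverse-logit predictions (random effects
at zero), clamped to (1e-15, 1−1e-15). Egg expectations per treatment and
cross type include the marginal lognormal factor exp(σ²/2) for the trial
intercept. Egg-model and survival-model chains are paired by index; unequal
lengths are thinned to the shortest (uncertainty propagation across the two
models is not specified by convention; index pairing of independent chains
is the neutral choice). The fitness weighting uses survival at zero and at
three competitors, three being the mean pre-infestation of infested seeds
in the behavioural arenas. p_MCMC is 2·min(fraction > 0, fraction < 0),
floored at 2/draws. Genotype means for the indirect-genetic-effects
ellipses take care = percent of a genotype's eggs on uninfested hosts per
treatment and survival = the egg-placement-weighted expected egg-to-adult
survival of those eggs; the 68% ellipse is the 1-sd contour from the
eigendecomposition of the 2x2 sample covariance across the six genotypes,
and the covariance sign is the IGE direction.

## Equilibrium load

Two habitats j (predictable) and k (unpredictable) at frequencies p_j,
1−p_j with productivities B_j, B_k contribute breeders in proportion to
p_i·B_i (soft selection), giving weights w_i and effective selection
s̄ = w_j s_j + w_k s_k. With genomic deleterious mutation rate U and
multiplicative loci, mutation–selection balance equilibrates the
segregating load where the contribution-weighted elimination rate matches
the input, so habitat mean fitness is W_i = exp(−U s_i/s̄) and load
L_i = 1 − W_i. In a homogeneous habitat this is Haldane–Muller: the load
depends on U alone (1 − e^(−U)). The dominance coefficient scales both the
per-allele selection and the equilibrium allele frequency inversely and
cancels from the genome-wide equilibrium load, which is why it is not a
parameter. The exact supplementary formulation behind the original figure
is not available in the source text; this form is isolated behind
`habitat_load` so an alternative can be swapped in, and only the
qualitative orderings (load rising with p_j, U, and B_j/B_k; W_j ≥ W_k
when s_j < s_k) are asserted. Default calibration: s_j = 0.48,
s_k = 1.33·s_j, U ∈ {1, 2}, B_j/B_k ∈ {1.96, 1}.

## Numerical and design choices

- Orthonormal polynomial bases (QR of the centred Vandermonde, signs fixed)
  for degree-2 terms; predictions and LRTs are coding-invariant, and raw
  coding gives identical statistics to 1e-6.
- Categorical factors use reference-level contrasts against the first level
  in sorted order.
- Random-number streams: every pipeline stage draws its seed from a
  `SeedSequence` spawn of the single global seed (all derived seeds below
  2^31), making runs byte-reproducible at the CSV level.
- Degenerate inputs: constant posterior series return zero-width intervals
  with a degeneracy flag; coincident or collinear genotype means flag a
  degenerate ellipse; zero outbred fitness or viability raises rather than
  returning infinities; Δω may legitimately be negative (inbred
  superiority) and is returned unclamped with a sign flag.
- Desk-scale problem sizes used by the test suite, chosen once: the demo
  pipeline runs 12 behavioural trials, 900 beans and 20,000-iteration
  chains; credible-interval coverage uses 400-bean replicates; the
  treatment-ordering check runs the full design with 4,000-iteration
  chains; the LRT null calibration uses 1,000 simulations of a 24-trial
  design. The acceptance script runs the full design sizes with the
  100,000/50,000/100 schedule.

## Known limitations

- Exact joint integration of more than one random factor is out of scope;
  the factor-by-factor approximation blurs the split between nested
  variance components (their sum, the fixed effects, and nested-model
  comparisons are well behaved).
- The sampler is random-walk Metropolis: adequate at these scales, but
  strongly correlated high-dimensional posteriors would mix slowly; no
  gradient-based samplers are provided.
- No REML, random slopes, overdispersion corrections, finite-population
  drift, migration–selection polymorphism, or antagonistic pleiotropy.
- The empty-table posterior (prior recovery) requires numeric-only fixed
  effects, since factor contrasts are undefined without observed levels.
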