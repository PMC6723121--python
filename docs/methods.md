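# Methods

`grouprr` simulates and analyses longitudinal feed-intake records in a
pedigreed pig population, with the analysis run either on individual
records or on pen-level records formed by summing the phenotypes of the
pen's currently present members.  This note describes the generative
model, the two random-regression models, the estimation machinery, and
the numerical and design choices behind them.

## Generative model

The population has discrete, non-overlapping generations.  Generation 0
holds unrelated founders (by default 30 males and 600 females at full
scale); each later generation is produced by randomly selecting 30 sires
and 600 dams from the previous generation, mating each sire to 20 dams,
one litter of 6 per dam (one parity per sow).  Selection and mating are
random, so no genetic trend develops.  Offspring sex is Bernoulli(1/2);
the constructor verifies that each generation can supply the required
sires and dams and raises otherwise.

Each phenotyped animal is measured at T = 6 weekly time points.  Time is
mapped affinely onto [-1, 1] and phi(x) denotes the normalized Legendre
covariates phi_k(x) = sqrt((2k+1)/2) P_k(x), k = 0, 1.  Additive genetic
and permanent-environment (PE) effects are curves with coefficient
vectors a_i, pe_i in R^2:

* founders: a_i ~ N(0, G);
* offspring: a_i = (a_s + a_d)/2 + m_i with Mendelian sampling
  m_i ~ N(0, (1/2)(1 - (F_s + F_d)/2) G), F the parents' inbreeding
  coefficients (computed exactly via the gene-flow decomposition
  A = T D T');
* pe_i ~ N(0, P) for phenotyped animals;
* records y_it = phi_t' a_i + phi_t' pe_i + e_it, e_it ~ N(0, sigma_e2),
  no interactions, zero trait mean, no simulated fixed effects.

Default generating values (the study's feed-intake trait):

    G = [[63.42, -5.42], [-5.42, 6.85]]
    P = [[30.61,  4.28], [ 4.28, 29.25]]
    sigma_e2 = 53.45

giving a heritability trajectory falling from 0.328 at week 1 to 0.214
at week 6 (`heritability_trajectory` reproduces these from G, P,
sigma_e2).  The absolute scale of G and P is tied to the normalized
Legendre convention; the unnormalized convention would rescale G and P
but leave h2(t) and every recovery property unchanged if applied
consistently to simulation and analysis, which is why a single
convention is used throughout.

Seeding: replicate k of a scenario derives five independent stage streams
(pedigree, breeding values, PE+residuals, pen assignment, drop-out) from
`SeedSequence([master_seed, k])`, so a replicate is reproducible in
isolation and stages can be varied independently.

## Pens and drop-out

Twelve same-generation phenotyped animals form a pen.  Three allocation
scenarios vary relatedness: `group3x4` (each litter randomly split into
two triples; a pen is 4 triples from 4 litters), `group6x2` (two whole
litters), `group1x12` (12 animals from 12 litters).  Litter-distinctness
constraints are met by a shuffle-then-repair swap procedure that is
deterministic given the stage seed.

Drop-out removes 15% of the phenotyped cohort.  `random`: round(0.15 N)
animals drawn uniformly, each with a drop-out time uniform on {1..6}.
`phenotypic`: at each time point t a count c_t ~ Poisson(0.15 N / 6) of
the currently lowest-phenotype animals (ranked at t, ties by id) is
removed — a proxy for culling poor performers, so the realized total is
stochastic.  Records from the drop-out time onward are missing, the
animal stops contributing to its pen's sum, and n_jt (the active group
size) shrinks; a fully emptied pen simply contributes no record.
Drop-out is planned on the phenotyped cohort, independent of pen
membership, so the individual- and group-data analyses of a replicate
see the same missingness.

## Statistical models

Individual records: y_it = phi_t' beta + phi_t' a_i + phi_t' pe_i + e_it
with a ~ N(0, A (x) G), pe ~ N(0, I (x) P), e ~ N(0, I sigma_e2); one
population fixed regression curve (the simulated mean is zero, so beta
mainly absorbs sampling noise).

Group records: summing the individual model over the active members of
pen j at time t gives y*_jt, whose additive/PE covariate row places
phi_t in the coefficient columns of every active member and whose
residual variance is n_jt sigma_e2 (R = D sigma_e2).  The fixed part is
one regression curve per observed group-size class m = n_jt.  A separate
group-size main effect plus size-nested intercepts would be confounded,
so the main effect is absorbed into the per-class curves; with a zero
true mean the alternative (n-scaled common curve) is immaterial, and the
size class uses the current active size, which is the only reading under
which classes m = 1..12 arise.  Animals whose every record is missing
keep their additive equations through the pedigree but get no PE
equations (PE is unidentifiable without records).

A^-1 is assembled directly from the pedigree by Henderson's rules with
inbreeding; unknown parents (founders only, closed population) are
treated as draws from the founder population.

## REML and BLUP machinery

Variance components theta = (G11, G12, G22, P11, P12, P22, sigma_e2) are
estimated by average-information REML through the mixed-model equations
(MME).  Per iteration the package computes, exactly:

* the deviance -2logL = log|C| + log|R| + log|A (x) G| + log|I (x) P|
  + y'Py via a sparse LDL' factorization of the MME matrix C;
* the score, whose trace terms tr(P dV/dtheta_i) reduce to sums of C^-1
  elements on the sparsity pattern of C — obtained from a selected
  inverse computed by the Takahashi recurrences on the filled pattern
  (no Monte-Carlo trace estimation);
* the AI matrix AI_ij = y' P V_i P V_j P y, which needs only solves
  against the factorized C.

Updates are Newton steps with the AI matrix and step halving so the
deviance never increases; a proposal outside the parameter space (G or P
not positive definite at an eigenvalue floor of 1e-8, or non-positive
residual variance) falls back to an EM-REML step for that iteration (EM
updates are always in-space).

Numerical choices worth knowing:

* scipy has no sparse symmetric factorization or selected inverse, so
  both are implemented here (numba-compiled, after Davis's up-looking
  LDL and the sparseinv-style Takahashi scheme with mirrored storage on
  the symmetrized filled pattern).  Dense linear algebra appears only in
  test oracles.
* Elimination order: A^-1 factors with zero fill when animals are
  eliminated youngest-first (its gene-flow factorization is triangular
  in pedigree order), so equations are ordered per animal (additive pair
  then PE pair), youngest animals first, dense fixed rows last.  For
  group designs, pen mates are eliminated consecutively (youngest pens
  first) because the summed records make each pen a clique; this roughly
  halves the fill again.  On the reduced-scale MME (~9,800 equations)
  this ordering yields ~10x less fill than SuperLU's minimum-degree
  ordering.
* The MME pattern is frozen across REML iterations by caching
  W'R0^-1 W (C = W'R0^-1 W / sigma_e2 + Sigma^-1 blocks): rebuilding it
  per iteration lets the numerically-zero Legendre intercept x slope
  cross-products drift in and out of the stored pattern.  For the same
  reason an exactly zero G12 or P12 is nudged by ~1e-10 relative before
  assembly, far below every tolerance used anywhere.
* Starting values: sigma_e2 = vp/2, G = P = diag(vp/4, vp/4T) with vp
  the raw phenotypic variance (for group records vp of y*/sqrt(n_jt),
  exact for unrelated pen mates).
* Convergence: relative parameter change < 1e-8 with gradient norm
  < 1e-6 (max 200 iterations).  When the optimum lies on the PD
  boundary of G or P — common for small datasets and for noisy pen-level
  data — the gradient cannot vanish and the EM fallback creeps; either
  three consecutive iterations with vanishing parameter change or three
  consecutive EM-fallback iterations improving the deviance by less than
  1e-6 relative then declare convergence with an `at_boundary` flag.
  Exceeding the iteration cap returns a result flagged unconverged
  rather than raising.

BLUP at the estimated (by default) or true (diagnostic flag) variance
components uses the same sparse factorization.  EBV(t) = phi_t' a_hat;
the selection index is the weight-1 sum of the six per-time-point EBVs,
i.e. (sum_t phi_t)' a_hat.  Validation over the animals with phenotypic
data (at least one observed record; for group data, at least one record
contributing to a pen sum) reports accuracy r = Pearson correlation of
estimated with true index and bias b1 = slope of regressing the true
index on the estimated index (1 = unbiased, > 1 = deflated EBVs).

## Problem sizes

Two profiles ship with the package.  The full-scale profile (11
generations of 30 sires x 20 dams x litter 6; 18,000 phenotyped animals
over the last 5 generations; 10 replicates per scenario) reproduces the
complete study design and is practical on a workstation but deliberately
not exercised by the test suite.  The reduced profile (6 generations of
10 sires x 10 dams x litter 6; 1,800 phenotyped animals over the last 3
generations; 5 replicates) preserves the structure — ~150 pens of 12,
the same drop-out rates, the same models — at roughly a tenth the cost,
and is what the test suite and the acceptance script run.  At this scale
an individual-model replicate (REML + BLUP + validation) takes a few
seconds and a group-model replicate up to about a minute.

## What the simulation does and does not emulate

The generator reproduces the study's stated conditions exactly: the
covariance structures above, random selection and mating, complete
pedigree recording, homogeneous residual variance, and no litter, pen or
social effects (all deliberately absent so the estimators see a
correctly specified model).  Real feed-intake data would add fixed
effects (herd, season), litter and pen environmental variance,
selection, heterogeneous residuals over the trajectory, and pedigree
errors; passing tests here demonstrate the estimation machinery and the
group-record model under the stated design, not robustness to those
violations.  Estimates from pen-summed records at the reduced scale are
individually noisy (the information loss from pooling is the point of
the comparison); conclusions are drawn from means over replicates.

## Known limitations

* First-order (intercept + slope) Legendre curves only are exercised,
  matching the study design; the basis code accepts higher orders but
  the 7-parameter REML packing is specific to order 1.
* No genetic groups for unknown parents, no genomic relationships, no
  multi-trait extension, no litter/pen/social random effects.
* The phenotypic drop-out ranks animals across the whole cohort (the
  natural reading of ranking "at each testing time point"); ranking
  within pens would be an alternative practical scenario.
* Boundary-constrained REML solutions are detected and flagged but not
  reparameterized away; interval estimates near the boundary should not
  be trusted at very small data sizes.
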