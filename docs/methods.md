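# Methods

This note documents the models the package implements, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Three-species coalescent likelihood

Each locus is an alignment of three sequences: two from the ingroup pair
(*S. invicta* and/or *S. richteri*; pair configurations II, RR, RI) and one
outgroup (*S. fugax*).  Times and diversities are scaled in expected
substitutions per site: the species splits sit at `tau_ir < tau_root`, and
each (ancestral) population carries a diversity parameter `theta`
(= 4·mu·Ne on the diploid scale) setting the pairwise coalescence rate
2/theta.

**Complete isolation** (`model="null"`): before `tau_ir` only same-species
pairs can coalesce; survivors coalesce in the ingroup ancestor on
(`tau_ir`, `tau_root`) at rate 2/theta_anc; if three lineages reach the
root, the first of the three possible pairs coalesces at total rate
6/theta_root, giving the two non-ingroup cherry topologies their
probability mass.

**Isolation with migration** (`model="im"`): before `tau_ir` the joint
location of the two ingroup lineages follows a 3-state continuous-time
Markov chain (both-in-invicta / split / both-in-richteri) with coalescence
as an absorbing event.  The scaled migration parameter M is defined so that
a lineage currently in species X relocates (backward in time) at rate
4·M/theta_X per unit mutational time; M = N·m in the usual
migrants-per-generation sense.  Transition probabilities come from an
eigendecomposition of the 3×3 transient generator (with a matrix-
exponential fallback when the eigenvector matrix is ill-conditioned).  The
null model is the M = 0 limit and the two constructions agree pointwise
there (tested).

**Alignment probability.**  JC69.  Under JC69 the likelihood of a site
depends only on its equality pattern, so an alignment enters the
computation through its five pattern-class counts (all equal, a=b, a=out,
b=out, all different); sites containing N are skipped.  Pattern-class
probabilities for a cherry at t1 and root at t0 are computed in closed
form; non-ingroup cherries are column permutations of the same kernel.

**Quadrature.**  The two coalescence-time integrals use K points per
dimension (default 16, the configuration used at production scale).  The
integrands mix two scales: coalescent densities decay at rate 2/theta
(hundreds per mutational unit) while the JC69 kernel varies at rate 4/3.
Semi-infinite exponential-weight integrals are therefore transformed to
v = exp(-4t/3), where the weight becomes an exact Beta(3·rate/4, 1) density
handled by a Gauss-Jacobi rule built by Golub-Welsch on the normalised
recurrence (stable for arbitrarily large Beta exponents, unlike forming the
unnormalised weights).  Finite intervals use Gauss-Legendre in v with the
exponential weight evaluated explicitly while `rate x span <= 30`, and fall
back to the Jacobi rule with nodes capped at the interval end beyond that
(truncated mass < 1e-13).  The migration-phase integral over (0, tau_ir)
is mapped linearly; its integrand is smooth at realistic parameter values
but this is the one rule whose accuracy degrades in extreme corners
(migration rates or coalescence rates >> 1/tau_ir).  Doubling K from 16 to
32 moves per-locus log-likelihoods by < 1e-4 at study-scale parameters
(tested), and the per-locus likelihood agrees with Monte-Carlo integration
over simulated gene trees within Monte-Carlo error (tested).

**Fitting.**  L-BFGS-B over log-transformed parameters (theta's, tau_ir,
tau_root - tau_ir, and for the IM model two directional migration rates),
method-of-moments initialisation from JC distances, multi-start with
log-normal jitter.  Because the log-migration gradient vanishes at the
M ~ 0 boundary, the IM fit always includes a migration-positive start, and
`fit_both()` additionally warm-starts the IM model from the isolation MLE
so the nesting inequality `lnL_IM >= lnL_null` holds numerically.

**LRT.**  `2·delta lnL` is referred to chi-square with df = 2 (two
directional migration rates; a single symmetric rate with df = 1 is
available).  With migration constrained non-negative the true null
distribution is a boundary mixture, so the chi-square reference is
conservative — observed type-I rates at nominal 5% are well below 5%
(tested at <= 10% over 50 null datasets).

**Identifiability at desk scale.**  With 96-bp loci at the published
parameter scale (tau_ir ~ 6.5e-4, theta ~ 4e-3) only ~25% of same-species
pairs coalesce before the split, so the contemporary theta's, tau_ir and
theta_anc individually sit on a likelihood ridge: at 2,000 loci their MLEs
wander tens of percent while the identifiable combinations — the expected
cross-species coalescence depth `tau_ir + theta_anc/2`, the root depth,
`tau_root` and `theta_root` — are recovered within ~10% (the test asserts
20%).  This is a property of the data regime, not the optimizer: the
fitted likelihood exceeds the likelihood at the truth.  Similarly, the
power of the LRT is intrinsically low when `tau_ir << theta` (an isolation
model with a smaller tau_ir absorbs most of the migration signal), which
is consistent with this data regime; the power test therefore uses a
contrast regime — contemporary theta's well below theta_anc, so tau_ir is
pinned by the same-species pairs, and moderate migration (M ~ 0.08), so
cross-species divergence is bimodal in a way no isolation parameterisation
can mimic.

## Four-population ABC

**Scenario.**  Backward in time: the introduced population (size N_I)
passes through a founder bottleneck of size N_F lasting T_B generations,
merges into the large native cluster at the introduction time T_I; the
second native cluster merges into the first at T_D >= T_I.  All sizes are
effective diploid-equivalent individuals; the haplodiploid 3/4 correction
is applied only at interpretation time (`theta = 3 mu Ne`).

**SNP scheme.**  One segregating site per locus: a single mutation is
placed on the genealogy with probability proportional to branch length.
Any non-root branch subtends a proper subset of the pooled sample, so every
locus is polymorphic in the pooled sample by construction (per-population
monomorphism still occurs and carries the founder signal).  No mutation
rate enters: genotype patterns depend on tree shape alone.

**Engines.**  `engine="hudson"` uses msprime (ploidy 2); `engine="fast"`
is a numba-compiled Kingman sampler specialised to this three-deme
piecewise history, used by default for reference tables where msprime's
per-replicate tree-sequence overhead dominates (~25 ms vs ~1.5 ms per
simulated dataset).  The two engines are cross-validated distributionally
on all 18 summary statistics (tested).

**Summary statistics (18).**  Per native cluster: proportion of
monomorphic loci, mean and variance of Nei's unbiased gene diversity over
polymorphic loci, mean gene diversity over all loci.  For the introduced
cluster only the monomorphic proportion and overall mean are used — a
newly founded, explosively growing population is poorly represented by the
higher moments.  For the two pairs that split directly from each other
(native1/native2, native1/introduced): mean per-locus Weir-Cockerham
F_ST, the proportion of "null" (<= 0) estimates, and mean and variance of
the positive remainder.  Negative per-locus estimates are retained for the
mean, not clipped; non-estimable (pooled-monomorphic) loci are excluded;
degenerate summaries report 0 so simulated vectors are always total.

**Priors.**  Introduction time uniform on 0–180 generations, founder size
uniform on 1–500, bottleneck length uniform on 0–40 (the ranges the study
states); draws violating T_B <= T_I <= T_D are rejected and resampled.
The remaining parameters get wide log-uniform priors spanning several
orders of magnitude (N_N1: 1e4–1e8, N_N2 and N_I: 1e3–1e7, T_D: 2e2–1e5);
these ranges are package configuration, chosen to bracket the published
point estimates by at least an order of magnitude each way, not values the
study reports.  Truncated-normal priors are supported as an alternative
family.

**Rejection and adjustment.**  Statistics are standardised by the
reference table's median absolute deviation (constant columns excluded
with a warning); the closest `ceil(tolerance x n)` simulations by
Euclidean distance are retained (ties by row index).  Retained parameters
are adjusted by weighted local-linear regression (Epanechnikov weights on
distance, statistics centred at the observation so the intercept is the
prediction there).  The pipeline regresses on a prior-support logit scale
(log scale first for log-uniform priors), which keeps adjusted particles
inside the support and accommodates the curvature of bounded parameters;
the raw-scale adjustment is available and is the form checked against the
exact-linear-recovery and normal-equations oracles.  MAP is the mode of a
weighted Gaussian KDE (Scott bandwidth, 512-point grid over the particle
range plus 5% padding); credible bounds are weighted 2.5%/97.5% quantiles.

**Goodness of fit.**  A random 10% of the simulated statistic vectors are
projected by PCA together with the observed vector; the report is the
percentile of the observed point's Mahalanobis distance within the
simulated cloud (0 = centre, 100 = outside).

**Calibration.**  Leave-one-out recovery on a 20,000-simulation table
(tolerance 1%, three 8-diploid samples, 100 loci): the 95% credible
interval covers the true N_F in >= 80% of 25 pseudo-observed replicates and
MAP(N_F) is rank-correlated with the truth (tested).  N_F is informative
only jointly with T_B (the data constrain the severity T_B/2N_F); T_I, N_I
and T_D remain close to their priors in this design, which the
`prior_posterior_overlap` diagnostic quantifies.

## Unit conversions

Generations = tau/mu with the hymenopteran pedigree rate
mu = 3.4e-9 (95% CI 2.2e-9–4.9e-9) per site per generation; intervals are
propagated by interval arithmetic (upper bound = tau_high/mu_low, lower =
tau_low/mu_high).  Years use a six-year generation time (plausible range
three to six).  Effective sizes: theta/(4 mu) diploid, theta/(3 mu)
haplodiploid.  Breeding groups: Ne = 4 Nf Nm/(Nf+Nm) for diploids and the
standard haplodiploid form Ne = 9 Nf Nm/(2 Nf + 4 Nm), which reduces to
Ne = 1.5 Nf under single mating (Nm = Nf); this is the relation the queen
counts rest on (it is sometimes misprinted with a 4 in the numerator,
which would give 2Nf/3 and contradict the 1.5 ratio).  Queen counts round
up: ceil(Ne/1.5), which maps 39 -> 26, 14 -> 10, 139 -> 93 exactly.
Display rounding is 2 significant figures.

## Synthetic data

`make_study_like_genotypes` draws a three-cluster SNP matrix (default ~40
samples x 1,500 loci, scalable) under a documented scenario: the native
clusters at the published sizes (1.2e7 and 2.5e5, two orders of magnitude
apart), founder size 39, introduction 90 generations ago, divergence
10,000 generations ago, contemporary introduced size 1e6.  The bottleneck
length is 16 generations — the upper bound of the published credible
interval rather than the 2-generation point estimate — because at severity
T_B/2N_F ~ 0.026 the founder signature would be statistically invisible in
1,500 loci, and a fixture whose defining property (introduced diversity
below native diversity) holds only in expectation over many regenerations
is not usable ground truth.  Depth is Poisson with gamma-distributed
per-sample mean coverage around 16x (so the 3-read mask fires), zero-depth
cells are missing, two designated samples carry ~35% missingness (so the
30% sample filter fires), and loci are spread over 16 contigs with 1.5–12
kb gaps (so 5-kb spacing thinning fires).  `make_triplet_fixture` simulates
triplet alignments at the published complete-isolation point estimates,
optionally with symmetric migration (default M = 2 for the gene-flow
variant).  All fixtures regenerate bit-for-bit from seed + manifest.

What the generator does **not** emulate: read-level error and allele
dropout (missingness is imposed at genotype level, independent of allele),
linkage between nearby loci (loci are exchangeable and unlinked, so spacing
thinning removes loci but no real LD), reference-mapping artefacts, and
population growth other than the stated size steps.  Passing tests
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to these real-data features.

## Numerical details and edge cases

- Pattern-class probabilities are floored at 1e-300 before logging so
  degenerate zero-branch trees keep `0 x log 0` well-defined.
- Genotype calls are int8 with MISSING = -1; all statistics exclude
  missing cells and loci with fewer than two gene copies in a population.
- Weir-Cockerham per-locus estimates are NaN where the estimator is
  undefined; the multi-locus `pairwise_fst` mean is the ratio of summed
  variance components (ratio-of-averages), while the ABC statistic block
  uses the mean of per-locus estimates, matching the two conventions'
  different uses.
- Greedy left-to-right keep-first spacing thinning is deterministic; ties
  in ABC rejection break by row index; the KDE MAP of identical particles
  is that value with a zero-width interval.
- Filters are projections (idempotent) and only change membership; the
  depth mask is the one stage that edits cells, and the pipeline skips it
  when the matrix carries no depth.
- Random-number contract: one integer seed determines a whole dataset;
  per-locus and per-simulation streams derive from `numpy.random.
  SeedSequence`; msprime and numba seeds are drawn below 2^31.

## Problem sizes used by the shipped experiments

Test-suite experiments run at desk scale by design: 20,000-simulation
reference tables with three 8-diploid samples and 100 loci; 50 null
datasets of 200 triplets for the LRT size check; 2,000 triplets for
parameter recovery; 1,000 RI-enriched triplets for power; 300 triplets for
quadrature convergence.  Production-scale settings (hundreds of thousands
of simulations, 15,040 triplets, 16,759-SNP matrices) are plain
configuration values on the same code paths.

## Known limitations

- JC69 only (configurable in principle; the pattern-class reduction relies
  on its symmetry, so richer models would need the full pruning kernel).
- No recombination within loci, no selection, no gene flow in the ABC
  scenario after the founding event.
- The LRT's chi-square reference is conservative at the M = 0 boundary; no
  parametric-bootstrap alternative is provided.
- Interval arithmetic treats the mutation-rate CI as hard bounds rather
  than resampling it.
- The migration-phase quadrature uses a linear map on (0, tau_ir) and can
  lose accuracy at parameter corners far outside the data-supported
  region.
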