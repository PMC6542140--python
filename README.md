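# fireant-demog

Coalescent demographic inference for the invasive fire ants *Solenopsis
invicta* and *S. richteri*: did the two species exchange genes since they
diverged in South America, and how many queens founded the North American
*S. invicta* population?

The package re-implements, as a tested library plus thin CLI, the two
inference engines such a study needs, together with everything around them
(RAD-seq SNP filtering, DIYABC-style summary statistics, coalescent
simulation, unit conversion, synthetic data, reporting):

1. **Isolation-with-migration likelihood test** on three-sequence
   alignments (two ingroup sequences, one outgroup).  Each 96-bp locus
   contributes

   `L = Σ_topologies ∫∫ f(G | τ, θ, M) · P(alignment | G) dt₁ dt₀`

   where `f` is the multispecies-coalescent gene-tree density (with
   migration between the two ingroup species modelled as a continuous-time
   Markov chain over lineage locations before the species split at τ_ir),
   `P` is the JC69 alignment probability, and the time integrals are done
   by Gauss-Legendre/Gauss-Jacobi quadrature (16 points per dimension by
   default).  A likelihood-ratio test compares complete isolation (M = 0)
   against isolation with migration.

2. **Approximate Bayesian computation** for a four-population history: two
   native clusters that split T_D generations ago, a founder population of
   effective size N_F derived from the first cluster T_I generations ago,
   a bottleneck of T_B generations, and the contemporary introduced
   population N_I.  Rejection sampling on 18 summary statistics (per-
   population gene-diversity moments and monomorphic proportions, pairwise
   Weir-Cockerham F_ST blocks) is followed by weighted local-linear
   regression adjustment, a kernel-density maximum-posterior estimate, 95%
   credible quantiles and a PCA goodness-of-fit check.

Scaled estimates convert to natural units via θ = 4μNe (diploid) or
θ = 3μNe (haplodiploid), τ/μ generations, and, for singly-mated
haplodiploid queens, Ne = 1.5·N_f, so a founder effective size maps to
⌈Ne/1.5⌉ unrelated queens.

## Worked example

```python
import dataclasses
from fireant_demog import (
    IMFitConfig, IsolationMigrationModel, TABLE1_PARAMS, make_triplet_fixture,
)

dataset, truth = make_triplet_fixture("null", n_loci=400, seed=1)
model = IsolationMigrationModel(dataset, IMFitConfig(n_starts=1, seed=0))
res_null, res_im, (delta, p) = model.fit_both()
print(f"delta lnL = {delta:.3f}, p = {p:.3f}")
print(res_null.summary())
```

prints (the fixture was simulated under complete isolation, so the
migration model earns essentially nothing and the test retains the null):

```
delta lnL = 0.000, p = 1.000
Model: complete isolation
log-likelihood: -62458.664037
n loci: 400

parameter             estimate
tau_ir             0.000790447
tau_root            0.00928035
theta_invicta       0.00745333
theta_richteri      0.00491338
theta_anc_ir        0.00163278
theta_root           0.0260927
```

`tau` values are expected substitutions per site since each split; with the
honey-bee mutation rate (3.4e-9 per site per generation) the fitted
`tau_root` ≈ 0.0093 corresponds to ~2.7 million generations.  Converting
the published estimates themselves:

```python
from fireant_demog import MutationRate, TABLE1_ESTIMATES, tau_to_generations

out = tau_to_generations(TABLE1_ESTIMATES["tau_ingroup_split"], MutationRate())
print(out)   # Interval(point=190000.0, low=110000.0, high=350000.0)
```

The ABC side, end-to-end on a synthetic observed dataset:

```python
from fireant_demog import FounderDemographyABC, make_study_like_genotypes

matrix, manifest = make_study_like_genotypes(seed=11)
results = FounderDemographyABC(matrix).fit(n_sims=20000, tolerance=0.01, seed=1)
print(results.summary())
```

The same stages are exposed as a CLI:
`fireant-demog synth|filter|sumstats|simulate|abc|imtest|convert|gof|report`.

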