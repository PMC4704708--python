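# hetwgp — whole-genome prediction with heteroskedastic residuals

Whole-genome prediction (WGP) regresses phenotypes on genome-wide SNP
dosages to predict the genetic merit of selection candidates.  Virtually
all of the classical "Bayesian alphabet" models — RR-BLUP, BayesA, BayesB,
BayesCπ — assume a single residual variance, yet in livestock data residual
variability routinely differs several-fold across sexes, herds or
slaughter-date groups.  Ignoring that heteroskedasticity biases breeding
values, most visibly for the extreme-ranked animals a breeding program
actually selects.

`hetwgp` is a toolkit for animal/plant breeders and quantitative
geneticists that fits the four classical WGP families under either the
usual homoskedastic residual or a hierarchical log-linear structural model
of the residual variance, and quantifies what the extra structure buys in
model fit, prediction accuracy and candidate ranking.

## The model

Mean model, for individual *i* with SNP dosages *z<sub>ij</sub>* ∈ {0,1,2}:

    y_i = x_i'β + Σ_j z_ij g_j  (+ u_i + d_q(i))  + e_i,   e_i ~ N(0, σ²_ei)

with marker-effect priors per family: g_j ~ N(0, σ²_g) (RR-BLUP), scaled
Student-t (BayesA), point-mass/Student-t mixture (BayesB) or
point-mass/normal mixture with unknown null probability π (BayesCπ);
optional polygenic effects u ~ N(0, A σ²_u) with a pedigree-derived
relationship matrix A, and normal cluster effects d.

Residual variance model (heteroskedastic specification):

    ln σ²_ei = w_i' ln τ + m_i' ln v,     v_l ~ IG(α_v, α_v − 1)

Under the set-to-zero parameterization the free τ components are variance
ratios between fixed strata (e.g. female-to-male); the v_l are relative
variances of environmental clusters with E(v_l) = 1 and
SD(v_l) = (α_v − 2)^(−1/2), so a small α_v means strong heteroskedasticity
and α_v → ∞ recovers the homoskedastic model.  Inference is by a
systematic-scan Gibbs sampler with conjugate scaled-inverse-χ² variance
updates and adaptive random-walk Metropolis steps for α_v, ν_g and the τ
ratios.  Competing specifications are compared by pseudo-Bayes factors
built from conditional predictive ordinates, by validation-set prediction
accuracy of genomic breeding values (GEBV), and by top/bottom-decile
Spearman rank agreement.

The package also ships the forward-in-time trait simulator used for
validation: a small population drifts to mutation-drift balance under
Poisson recombination and recurrent biallelic mutation, loci are filtered
on minor allele frequency and exact Hardy-Weinberg tests, heavy-tailed QTL
effects define true breeding values at h² = 0.4, and phenotypes receive
structurally heteroskedastic residuals over a gradient α_v ∈
{3, 5, 12, 50, ∞} with τ₁/τ₂ = 0.8.

## Worked example

```python
import numpy as np
from hetwgp import SimScenario, simulate_dataset, ModelSpec, McmcSpec, fit
from hetwgp.experiments import training_data_from_simulation
from hetwgp.evaluation import (gebv, prediction_accuracy, log10_pbf,
                               hpd_interval, spearman_extremes)

scenario = SimScenario.desk(alpha_v=3.0)      # strong heteroskedasticity
ds = simulate_dataset(scenario, seed=1)
data = training_data_from_simulation(ds)
mcmc = McmcSpec(n_burnin=800, n_iter=2500, thin=1, seed=7)

homo = fit(data, ds.training, ModelSpec("rrblup", heteroskedastic=False), mcmc)
het  = fit(data, ds.training, ModelSpec("rrblup", heteroskedastic=True), mcmc)

gebv_ho = gebv(homo, ds.validation)
gebv_ht = gebv(het, ds.validation)
print("accuracy (homoskedastic): %.3f" % prediction_accuracy(ds.tbv_validation, gebv_ho))
print("accuracy (heteroskedastic): %.3f" % prediction_accuracy(ds.tbv_validation, gebv_ht))
print("log10 PBF(HT, HO): %.1f" % log10_pbf(het, homo))
print("posterior mean of alpha_v: %.2f (true 3)" % np.mean(het["alpha_v"]))
print("tau1/tau2 95%% HPD: (%.2f, %.2f) (true 0.8)" % hpd_interval(het["tau"][:, 1]))
print("top-decile Spearman HO vs HT: %.2f" % spearman_extremes(gebv_ho, gebv_ht)[0])
```

which prints

```
accuracy (homoskedastic): 0.814
accuracy (heteroskedastic): 0.824
log10 PBF(HT, HO): 9.7
posterior mean of alpha_v: 4.15 (true 3)
tau1/tau2 95% HPD: (0.63, 1.07) (true 0.8)
top-decile Spearman HO vs HT: 0.85
```

The heteroskedastic fit is decisively favored (log₁₀PBF ≈ 10), gains about
one accuracy point on one-generation-removed validation animals, recovers
the variance hyperparameters, and reranks the top decile of candidates
noticeably (Spearman 0.85 rather than ≈ 1).

A command-line interface mirrors the library:

```bash
hetwgp simulate --config scenario.yaml --seed 3 --out-dir sim/
hetwgp fit --model rrblup --hetero --genotypes sim/training_genotypes.csv \
           --phenotypes sim/phenotypes.csv --variance-group tau_group \
           --variance-cluster v_level --seed 1 --out samples.npz
hetwgp predict --samples samples.npz --genotypes sim/validation_genotypes.csv --out gebv.csv
hetwgp pbf --samples-ht ht.npz --samples-ho ho.npz
hetwgp reproduce-sim --scale desk --out-dir results/
```

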