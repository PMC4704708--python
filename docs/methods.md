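# Methods

## Model

For phenotypes `y_i` (i = 1..n) and minor-allele dosages `z_ij` ∈ {0,1,2}
(j = 1..p):

    y_i = x_i' beta + sum_j z_ij g_j (+ u_i + d_q(i)) + e_i
    e_i ~ N(0, sigma2_ei)

The marker-effect prior defines the family:

| family  | prior on g_j |
|---------|--------------|
| RR-BLUP | N(0, sigma2_g), common variance |
| BayesA  | N(0, sigma2_gj), sigma2_gj ~ chi^-2(nu_g, nu_g s2_g) (marginally scaled Student-t) |
| BayesB  | point mass at 0 with probability pi, else the BayesA slab |
| BayesCpi| point mass at 0 with probability pi, else N(0, sigma2_g) |

Optional terms for observational data: polygenic effects
`u ~ N(0, A sigma2_u)` with A built from the pedigree by the tabular
method, and mean-model cluster effects `d_q ~ N(0, sigma2_d)` (e.g.
slaughter dates).

The residual variance is either a single `sigma2_e` (homoskedastic) or
the log-linear structural model

    ln sigma2_ei = w_i' ln tau + m_i' ln v,   v_l ~ IG(alpha_v, alpha_v - 1)

`W` uses a set-to-zero parameterization: column 0 is an all-ones baseline
whose tau component is the reference residual variance; every further
column is a 0/1 stratum indicator whose tau component is a variance
ratio.  The inverted-gamma shape/scale coupling gives `E(v_l) = 1` and
`Var(v_l) = 1/(alpha_v - 2)`, so `alpha_v` is a single interpretable
heteroskedasticity dial; its support is restricted to (2, inf) so the
variance exists, and `alpha_v -> inf` collapses the model to
homoskedasticity.

### Priors

Flat prior on `beta`.  All free variances (`sigma2_e`, `sigma2_g`, `s2_g`,
`sigma2_d`, the tau components) carry the improper reference density
`p(variance) ∝ variance^(-1/2)` — uniform on the standard deviation —
whose conjugate update is a scaled-inverse-chi-square with `count - 1`
degrees of freedom.  `pi` is the probability of a *null* marker with a
Beta(10, 1) prior (prior mean ≈ 0.91 null).  `nu_g` and `alpha_v` carry
`p(x) ∝ (1 + x)^-2`, i.e. a uniform density on `1/(1 + x)`.  For
identifiability in observational workflows, `sigma2_u` (and for the
variable-selection families `s2_g` or `sigma2_g`) can be pinned to
externally estimated constants via `ModelSpec.fixed_hyperparams`.

## Sampler

Systematic-scan Gibbs with the update order: beta → markers (sequential,
residual maintained by subtract/add-back) → marker variances → pi /
Student-t hyperparameters → u → d → sigma2_d → tau → v → alpha_v →
sigma2_e (homoskedastic only).  Design points:

- **Marker scans** run in a compiled (numba) kernel.  For the mixture
  families the inclusion indicator is drawn from the two-point posterior
  with the effect integrated out analytically:
  `BF_j = sqrt(lam_j / C_j) exp(r_j^2 / 2 C_j)` with `C_j = sum_i
  omega_i z_ij^2 + lam_j`, `lam_j` the slab precision and `r_j` the
  weighted partial-residual projection.  A zero-variance marker column
  contributes no likelihood and its effect is drawn from the prior (with
  a warning).
- **tau**: the baseline component is conjugate given the multiplicative
  remainder of `sigma2_ei`; each ratio component uses Gaussian
  random-walk Metropolis on its logarithm.  `alpha_v` walks on
  `ln(alpha_v - 2)` and `nu_g` on `ln nu_g`, with the Jacobian in the
  acceptance ratio.  Step sizes adapt every 50 proposals toward ~35%
  acceptance during burn-in and are frozen afterwards.
- **v** is exactly conjugate:
  `v_l | · ~ IG(alpha_v + n_l/2, (alpha_v - 1) + ½ sum e_i^2 / t_i)` with
  `t_i = exp(w_i' ln tau)`; empty clusters refresh from the prior.
- **Degenerate conjugate draws** (e.g. all included effects exactly zero)
  floor the scale at `1e-12 · Var(y)` so the chain stays on its support
  without informing the posterior.
- In BayesB, excluded markers' `sigma2_gj` are refreshed from their prior
  each scan, and the `nu_g`/`s2_g` conditionals therefore include all
  marker variances currently in the state.
- Multiple chains disperse initial hyperparameters by a small
  multiplicative factor; per-observation Gaussian log-likelihoods are
  stored at every saved iteration for predictive-ordinate computation.

Default chain budget (`McmcSpec`): 2,000 burn-in, 4,000 saved, thin 2.
The desk-scale studies below use 400–800 burn-in and 1,000–2,500 saved
draws, which give effective sample sizes comfortably above 100 for the
variance hyperparameters at those data sizes.

## Model comparison and prediction

Conditional predictive ordinates use the harmonic-mean identity
`CPO_i = (mean_b 1/L(y_i|theta_b))^-1`, evaluated by log-sum-exp because
the estimator is dominated by the smallest likelihood draws.  The
pseudo-Bayes factor is `log10 PBF = sum_i log10 CPO_i(HT) - sum_i log10
CPO_i(HO)`; positive values favor the heteroskedastic specification.
GEBV are linear combinations of posterior-mean marker effects (plus
posterior-mean polygenic effects when present); point predictions never
use posterior-predictive simulation.  Cross-validation folds are
stratified within clusters (shuffle, deal cyclically from a random
starting fold), so per-cluster fold counts differ by at most one.
Extreme-rank agreement is the Spearman correlation restricted to the top
(bottom) decile ranked by the first GEBV vector, ties resolved by stable
index order.  HPD intervals are shortest sorted-sample windows.
Convergence checks (ESS, Gelman-Rubin) delegate to ArviZ with the
conventional thresholds ESS > 100 and shrink factor < 1.2.

## Simulator

The generator reproduces the validation design end to end:

1. **Drift.** A population of `n_founders` diploids, initially monomorphic
   at `loci_per_chromosome` equally spaced loci per chromosome (positions
   `(j - ½)/L` Morgans), mates randomly for `n_generations`.  Each
   meiosis draws Poisson(1) crossovers per chromosome, uniform crossover
   positions, a fair-coin starting strand, and recurrent (state-flipping,
   hence always biallelic) mutations at `2.5e-4` per locus per
   generation.  Long runs reach mutation-drift balance; for the symmetric
   two-allele flip model the stationary allele frequency is
   Beta(alpha, alpha) with `alpha = 4 N mu`, giving expected
   heterozygosity `alpha/(2 alpha + 1)` — a closed form the test suite
   checks against a scaled run.
2. **Expansion and filtering.** The final generation is expanded by
   random mating into the training generation; loci with MAF < 0.1 or an
   exact two-sided Hardy-Weinberg p-value < 1e-4 (conditional-on-allele-
   counts enumeration) are discarded, and disjoint QTL and marker panels
   are sampled from the survivors.
3. **Trait.** QTL substitution effects are scaled Student-t draws with 5
   degrees of freedom and squared scale 0.005 (`Var(a_k) = s^2 df/(df-2)`;
   the scale parameter is interpreted as the squared scale, consistent
   with the `t(0, s^2)` notation used for the marker priors).  The
   additive variance is `sigma2_a = 2 sum_k q_k (1-q_k) a_k^2`; the
   reference residual variance follows from h^2 = 0.4; true breeding
   values are exact dosage-weighted sums.
4. **Phenotypes.** Individuals are assigned to two tau groups and 50 v
   clusters by balanced random assignment (the assignment scheme is not
   dictated by the design; balance maximizes identifiability),
   `sigma2_ei = tau_group * v_level` with `tau_2` the reference variance
   and `tau_1 = 0.8 tau_2`, and `y_i = 3 + TBV_i + e_i`.  When
   `alpha_v = inf` both tau groups share the reference variance and all
   `v_l = 1`.
5. **Validation.** One further random-mating generation supplies
   genotypes and TBV only — prediction accuracy is measured one
   generation removed from training.

Identical scenario + seed reproduce a dataset bit for bit, and one genome
replicate can be shared across the whole `alpha_v` gradient
(`simulate_genomes` / `simulate_dataset`), so the residual-variance
scenarios are compared on common genetic material, as a blocking factor.

### Scales

The default `SimScenario` is the full design (150 founders, 6,000
generations, 3 × 10,000 loci, 1,500 individuals, 60 QTL, 3,000 markers).
`SimScenario.desk()` preserves the structure and the n/p regime at sizes
that run in seconds: 50 founders, 1,000 generations, 3 × 3,000 loci, 600
individuals, 12 QTL, 600 markers.  Desk-scale genomes have higher
adjacent-marker linkage disequilibrium (r² ≈ 0.3 rather than ≈ 0.24)
because the drifting population is smaller; the heteroskedasticity
conditions (alpha_v gradient, tau ratio, h², 50 clusters) are unchanged.
All study-level tests and `scripts/acceptance.py` use desk scale.

### What the simulation does and does not establish

Passing the desk-scale studies shows the samplers recover structural
heteroskedasticity, that pseudo-Bayes factors track its true magnitude,
and that accounting for it yields small accuracy gains and non-trivial
reranking of extreme candidates under the stated generative conditions.
It does not certify behavior on real data, where heteroskedasticity can
be confounded with preferential treatment or genetic variance
heterogeneity, where genotypes contain imputation error, and where LD
structure is shaped by selection — none of which the generator emulates.

## Numerical choices and edge cases

- Harmonic-mean CPO in log space (log-sum-exp); non-finite likelihood
  draws raise with the offending iteration.
- Metropolis transforms keep parameters on their support
  (`alpha_v > 2`, positive variances); the degenerate all-null marker
  state is floored as described above.
- Pedigrees are topologically sorted before the tabular A-matrix
  recursion (parents must precede offspring); cycles raise.
- Missing genotypes are a hard error by default, with an opt-in rounded
  column-mean imputation for pre-cleaned panels.
- Single-level variance factors without clusters reduce the model to
  homoskedasticity and warn rather than fail.
- HWE exact p-values use the conditional distribution of the heterozygote
  count given allele counts; the comparison with the observed
  configuration carries a `1 + 1e-12` relative guard against ties lost to
  rounding.

## Known limitations

- The polygenic update solves a dense system per scan; populations beyond
  a few thousand pedigree members would need sparse inverse-relationship
  machinery, which is out of scope.
- No EM/variational accelerations, WAIC/PSIS-LOO, multi-breed
  heterogeneous genetic variances, or Student-t robust residuals; the
  residual-variance model is environmental only (no genetic control of
  variance).
- The forward simulator is not a coalescent: full-scale (6,000
  generation) runs are possible but slow; the desk scale is the intended
  regime for routine validation.
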