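"""Forward-in-time simulation of genomes and heteroskedastic phenotypes.

A small constant-size population drifts to mutation-drift balance under
random mating, per-chromosome Poisson recombination and recurrent biallelic
mutation; the final generation is expanded into a training generation whose
loci are filtered on minor allele frequency and Hardy-Weinberg equilibrium
and split into QTL and SNP marker panels.  QTL substitution effects are
heavy-tailed (scaled Student-t), phenotypes add a residual whose variance is
a multiplicative function of a two-level fixed factor (``tau``) and of
cluster relative variances ``v_l ~ IG(alpha_v, alpha_v - 1)``; a further
random-mating generation supplies genotypes and true breeding values for
validation one generation removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from hetwgp.datamodel import GenotypeMatrix, compute_maf

__all__ = [
    "SimScenario",
    "SimulatedDataset",
    "meiosis",
    "evolve_base_population",
    "random_mating",
    "hwe_exact_test",
    "hwe_exact_pvalues",
    "filter_and_assign_loci",
    "draw_trait_architecture",
    "generate_phenotypes",
    "adjacent_marker_ld",
    "simulate_genomes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimScenario:
    """Full generative configuration for one simulation replicate.

    Defaults are the reference study conditions: 150 founders drifting for
    6000 generations, three 1-Morgan chromosomes of 10,000 equally spaced
    loci, recurrent mutation at 2.5e-4 per locus per generation, MAF >= 0.1
    and exact-HWE (alpha 1e-4) filtering at the expanded generation, 60
    t5-distributed QTL, 3000 markers, h2 = 0.4 and a heteroskedasticity
    gradient indexed by ``alpha_v`` (``inf`` = homoskedastic) with fixed
    variance ratio ``tau_ratio = 0.8`` across two groups.  ``desk()``
    returns a scaled-down configuration preserving the n/p regime.
    """

    n_founders: int = 150
    n_generations: int = 6000
    expansion_size: int = 1500
    n_chromosomes: int = 3
    chrom_length: float = 1.0
    loci_per_chromosome: int = 10_000
    mutation_rate: float = 2.5e-4
    maf_threshold: float = 0.1
    hwe_alpha: float = 1e-4
    n_qtl: int = 60
    n_markers: int = 3000
    qtl_effect_df: float = 5.0
    qtl_effect_scale: float = 0.005  # squared scale s^2 of the t distribution
    h2: float = 0.4
    mu: float = 3.0
    alpha_v: float = 3.0
    tau_ratio: float = 0.8
    n_v_levels: int = 50

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "expansion_size",
                     "n_chromosomes", "loci_per_chromosome", "n_qtl",
                     "n_markers", "n_v_levels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if np.isfinite(self.alpha_v) and self.alpha_v <= 2.0:
            raise ValueError("alpha_v must exceed 2 (or be inf) so Var(v) exists")
        if self.tau_ratio <= 0:
            raise ValueError("tau_ratio must be positive")

    @classmethod
    def desk(cls, alpha_v: float = 3.0, **overrides) -> "SimScenario":
        """Desk-scale configuration: same structure, minutes not days."""
        base = dict(
            n_founders=50,
            n_generations=1000,
            expansion_size=600,
            loci_per_chromosome=3000,
            n_qtl=12,
            n_markers=600,
            alpha_v=alpha_v,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def positions(self) -> np.ndarray:
        """Within-chromosome genetic positions (Morgans), equally spaced."""
        j = np.arange(self.loci_per_chromosome) + 0.5
        per_chrom = j / self.loci_per_chromosome * self.chrom_length
        return np.tile(per_chrom, self.n_chromosomes)

    @property
    def chrom_bounds(self) -> np.ndarray:
        return np.arange(self.n_chromosomes + 1) * self.loci_per_chromosome

    @property
    def chromosomes(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chromosomes), self.loci_per_chromosome)


@dataclass
class SimulatedDataset:
    """Training and validation material plus the generative truth."""

    training: GenotypeMatrix          # marker panel, generation G+1
    y: np.ndarray
    tbv: np.ndarray
    tau_group: np.ndarray             # 1 or 2 per training individual
    v_level: np.ndarray               # 0..n_v_levels-1 per training individual
    validation: GenotypeMatrix        # marker panel, generation G+2
    tbv_validation: np.ndarray
    qtl_effects: np.ndarray
    sigma_a2: float
    sigma_e2_star: float
    v_true: np.ndarray
    sigma2_ei: np.ndarray
    qtl_idx: np.ndarray
    marker_idx: np.ndarray
    scenario: SimScenario = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# meiosis and drift
# ---------------------------------------------------------------------------

def meiosis(
    parent: np.ndarray,
    positions: np.ndarray,
    chrom_bounds: np.ndarray,
    chrom_length: float,
    mutation_rate: float,
    rng: np.random.Generator,
    n_crossovers: Optional[int] = None,
) -> np.ndarray:
    """One gamete from a (2, L) parental haplotype pair.

    Per chromosome the crossover count is Poisson(1) (overridable via
    ``n_crossovers``), crossover locations are uniform on the chromosome,
    the starting strand is a fair coin, and the gamete switches strands at
    each crossover.  Mutation then flips each locus independently with
    probability ``mutation_rate`` (recurrent, biallelic).
    """
    parent = np.asarray(parent)
    L = parent.shape[1]
    gamete = np.empty(L, dtype=parent.dtype)
    for c in range(len(chrom_bounds) - 1):
        lo, hi = chrom_bounds[c], chrom_bounds[c + 1]
        k = rng.poisson(1.0) if n_crossovers is None else n_crossovers
        points = np.sort(rng.uniform(0.0, chrom_length, size=k))
        start = rng.integers(2)
        strand = (start + np.searchsorted(points, positions[lo:hi], side="right")) % 2
        gamete[lo:hi] = parent[strand, np.arange(lo, hi)]
    if mutation_rate > 0:
        flips = rng.random(L) < mutation_rate
        gamete[flips] ^= 1
    return gamete


@njit(cache=True)
def _mate_kernel(haps, n_off, bounds, pos, clen, mu, seed):  # pragma: no cover
    np.random.seed(seed)
    n_par = haps.shape[0]
    L = haps.shape[2]
    nc = bounds.shape[0] - 1
    out = np.empty((n_off, 2, L), dtype=np.uint8)
    for k in range(n_off):
        p1 = np.random.randint(0, n_par)
        p2 = np.random.randint(0, n_par)
        while p2 == p1 and n_par > 1:
            p2 = np.random.randint(0, n_par)
        for which in range(2):
            par = p1 if which == 0 else p2
            for c in range(nc):
                lo = bounds[c]
                hi = bounds[c + 1]
                nx = np.random.poisson(1.0)
                xp = np.empty(nx)
                for m in range(nx):
                    xp[m] = np.random.random() * clen
                xp = np.sort(xp)
                strand = 0 if np.random.random() < 0.5 else 1
                m = 0
                for j in range(lo, hi):
                    while m < nx and xp[m] <= pos[j]:
                        strand = 1 - strand
                        m += 1
                    out[k, which, j] = haps[par, strand, j]
            # recurrent mutation: Binomial(L, mu) flips at uniform loci
            # (position collisions are vanishingly rare at mu*L ~ 1)
            nm = np.random.binomial(L, mu)
            for _ in range(nm):
                j = np.random.randint(0, L)
                out[k, which, j] = 1 - out[k, which, j]
    return out


def random_mating(
    haps: np.ndarray, n_offspring: int, scenario: SimScenario, seed: int
) -> np.ndarray:
    """One generation of random mating (distinct parents per offspring)."""
    return _mate_kernel(
        np.ascontiguousarray(haps, dtype=np.uint8),
        n_offspring,
        scenario.chrom_bounds.astype(np.int64),
        scenario.positions,
        scenario.chrom_length,
        scenario.mutation_rate,
        np.uint32(seed),
    )


def evolve_base_population(scenario: SimScenario, seed: int) -> np.ndarray:
    """Drift an initially monomorphic population for ``n_generations``.

    Returns the (n_founders, 2, L) haplotype array of the final drift
    generation, at approximate mutation-drift balance for long runs.
    """
    ss = np.random.SeedSequence(seed)
    gen_seeds = ss.generate_state(scenario.n_generations)
    haps = np.zeros((scenario.n_founders, 2, scenario.n_loci), dtype=np.uint8)
    for g in range(scenario.n_generations):
        haps = random_mating(haps, scenario.n_founders, scenario, gen_seeds[g])
    return haps


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (conditional on allele counts).

    p is the total probability, under the exact conditional distribution of
    the heterozygote count given the allele counts, of all configurations
    no more probable than the observed one.  A monomorphic sample gives 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be nonnegative with n >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # rarer-or-not does not matter; test is symmetric
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (n_a + hets) / 2 + 1)
        + hets * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def hwe_exact_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per locus of an (n, p) dosage matrix."""
    dosages = np.asarray(dosages)
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        n2 = int(np.sum(col == 2))
        n1 = int(np.sum(col == 1))
        n0 = col.shape[0] - n1 - n2
        out[j] = hwe_exact_test(n0, n1, n2)
    return out


# ---------------------------------------------------------------------------
# locus filtering and trait architecture
# ---------------------------------------------------------------------------

def filter_and_assign_loci(
    dosages: np.ndarray, scenario: SimScenario, rng: np.random.Generator
):
    """Apply MAF/HWE filters, then sample disjoint QTL and marker sets.

    Loci with MAF below ``maf_threshold`` or exact-HWE p-value below
    ``hwe_alpha`` are discarded; ``n_qtl`` QTL and ``n_markers`` markers are
    drawn without replacement from the survivors.
    """
    maf = compute_maf(dosages)
    candidate = maf >= scenario.maf_threshold
    idx = np.flatnonzero(candidate)
    pvals = hwe_exact_pvalues(dosages[:, idx])
    keep = idx[pvals >= scenario.hwe_alpha]
    need = scenario.n_qtl + scenario.n_markers
    if keep.size < need:
        raise RuntimeError(
            f"only {keep.size} loci survive filtering but {need} are needed; "
            "increase the genome size or relax the MAF/HWE thresholds"
        )
    chosen = rng.choice(keep, size=need, replace=False)
    qtl_idx = np.sort(chosen[: scenario.n_qtl])
    marker_idx = np.sort(chosen[scenario.n_qtl:])
    return qtl_idx, marker_idx, keep


def draw_trait_architecture(
    qtl_dosages: np.ndarray, scenario: SimScenario, rng: np.random.Generator
):
    """Draw QTL substitution effects and derive the variance components.

    Effects are iid scaled Student-t with ``qtl_effect_df`` degrees of
    freedom and squared scale ``qtl_effect_scale`` (so Var(a_k) =
    s^2 * df / (df - 2)).  The additive variance is the HWE-weighted sum
    ``sigma_a2 = 2 sum q_k (1 - q_k) a_k^2`` over QTL minor allele
    frequencies ``q_k``; the reference residual variance follows from the
    target heritability, ``sigma_e2_star = sigma_a2 (1 - h2) / h2``; and
    the true breeding value is the exact linear combination of dosages.
    """
    q = compute_maf(qtl_dosages)
    a = rng.standard_t(scenario.qtl_effect_df, size=qtl_dosages.shape[1])
    a *= math.sqrt(scenario.qtl_effect_scale)
    sigma_a2 = float(2.0 * np.sum(q * (1.0 - q) * a**2))
    if sigma_a2 <= 0.0:
        raise ValueError("all QTL effects are null; residual variance undefined")
    sigma_e2_star = sigma_a2 * (1.0 - scenario.h2) / scenario.h2
    tbv = qtl_dosages @ a
    return a, tbv, sigma_a2, sigma_e2_star


def generate_phenotypes(
    tbv: np.ndarray, scenario: SimScenario, sigma_e2_star: float,
    rng: np.random.Generator,
):
    """Phenotypes ``y = mu + TBV + e`` with structurally heteroskedastic e.

    Cluster relative variances ``v_l`` are iid IG(alpha_v, alpha_v - 1)
    (identically 1 when alpha_v is inf, the homoskedastic limit, in which
    case the two tau groups also share the reference variance).  Each
    individual receives one of two tau groups and one of ``n_v_levels``
    clusters by balanced random assignment, and
    ``sigma2_ei = tau_group(i) * v_level(i)`` with ``tau_2 =
    sigma_e2_star`` and ``tau_1 = tau_ratio * sigma_e2_star``.
    """
    if sigma_e2_star <= 0:
        raise ValueError("sigma_e2_star must be positive")
    n = len(tbv)
    av = scenario.alpha_v
    if np.isinf(av):
        v_true = np.ones(scenario.n_v_levels)
        taus = np.array([sigma_e2_star, sigma_e2_star])
    else:
        if av <= 2.0:
            raise ValueError("alpha_v must exceed 2: Var(v) would not exist")
        # IG(a, b) via b / Gamma(a); E(v)=1, Var(v)=1/(a-2) at b = a-1
        v_true = (av - 1.0) / rng.gamma(av, size=scenario.n_v_levels)
        taus = np.array([scenario.tau_ratio * sigma_e2_star, sigma_e2_star])
    tau_group = np.ones(n, dtype=np.int64)
    tau_group[n // 2:] = 2
    rng.shuffle(tau_group)
    v_level = np.arange(n) % scenario.n_v_levels
    rng.shuffle(v_level)
    sigma2_ei = taus[tau_group - 1] * v_true[v_level]
    e = rng.normal(0.0, np.sqrt(sigma2_ei))
    y = scenario.mu + tbv + e
    return y, tau_group, v_level, v_true, sigma2_ei


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def adjacent_marker_ld(dosages: np.ndarray, chromosomes: np.ndarray) -> float:
    """Mean squared Pearson correlation between adjacent marker dosages.

    Pairs are formed within chromosome between physically adjacent marker
    columns; zero-variance columns are skipped with a warning.
    """
    import warnings

    dosages = np.asarray(dosages, dtype=float)
    chromosomes = np.asarray(chromosomes)
    r2 = []
    skipped = 0
    for c in np.unique(chromosomes):
        cols = np.flatnonzero(chromosomes == c)
        for a, b in zip(cols[:-1], cols[1:]):
            x, ycol = dosages[:, a], dosages[:, b]
            if x.std() == 0.0 or ycol.std() == 0.0:
                skipped += 1
                continue
            r2.append(np.corrcoef(x, ycol)[0, 1] ** 2)
    if skipped:
        warnings.warn(f"skipped {skipped} adjacent pairs with zero variance",
                      stacklevel=2)
    if not r2:
        raise ValueError("no valid adjacent marker pairs")
    return float(np.mean(r2))


# ---------------------------------------------------------------------------
# end-to-end replicate
# ---------------------------------------------------------------------------

def _dosage_minor(train_haps: np.ndarray, other_haps: np.ndarray):
    """Dosages of the minor allele, oriented on training frequencies."""
    train_counts = train_haps.sum(axis=1).astype(np.int8)
    other_counts = other_haps.sum(axis=1).astype(np.int8)
    freq1 = train_counts.mean(axis=0) / 2.0
    flip = freq1 > 0.5
    train_counts[:, flip] = 2 - train_counts[:, flip]
    other_counts[:, flip] = 2 - other_counts[:, flip]
    return train_counts, other_counts


def simulate_genomes(scenario: SimScenario, seed: int):
    """Drift, expand into the training generation, and mate once more.

    Returns minor-allele dosage matrices ``(train, validation)`` over all
    simulated loci.  This stage depends only on the genome-shaping fields
    of the scenario, so one genome replicate can serve as the blocking
    factor across the whole heteroskedasticity gradient.
    """
    ss = np.random.SeedSequence([seed, 0xB10])
    s_drift, s_expand, s_valid, _ = ss.spawn(4)
    base = evolve_base_population(scenario, s_drift.generate_state(1)[0])
    train_haps = random_mating(
        base, scenario.expansion_size, scenario, s_expand.generate_state(1)[0]
    )
    valid_haps = random_mating(
        train_haps, scenario.expansion_size, scenario, s_valid.generate_state(1)[0]
    )
    return _dosage_minor(train_haps, valid_haps)


def simulate_dataset(
    scenario: SimScenario, seed: int, genomes=None
) -> SimulatedDataset:
    """Run one full replicate of the generative design.

    Drift -> expansion into the training generation -> MAF/HWE filtering
    and QTL/marker assignment -> trait architecture -> heteroskedastic
    phenotypes -> one further random-mating generation for validation.
    Identical scenario and seed reproduce the dataset bit for bit.
    Precomputed ``genomes`` from :func:`simulate_genomes` (same seed) may
    be passed to share one genome across residual-variance scenarios.
    """
    ss = np.random.SeedSequence([seed, 0xB10])
    _, _, _, s_rest = ss.spawn(4)
    if genomes is None:
        genomes = simulate_genomes(scenario, seed)
    train_dose, valid_dose = genomes
    rng = np.random.default_rng(s_rest)
    qtl_idx, marker_idx, _ = filter_and_assign_loci(train_dose, scenario, rng)
    a, tbv, sigma_a2, sigma_e2_star = draw_trait_architecture(
        train_dose[:, qtl_idx], scenario, rng
    )
    tbv_valid = valid_dose[:, qtl_idx] @ a
    y, tau_group, v_level, v_true, sigma2_ei = generate_phenotypes(
        tbv, scenario, sigma_e2_star, rng
    )
    chroms = scenario.chromosomes
    pos = scenario.positions

    def _panel(dose, prefix):
        ids = np.array([f"{prefix}{i + 1}" for i in range(dose.shape[0])],
                       dtype=object)
        mp = pd.DataFrame({
            "chromosome": chroms[marker_idx],
            "position": pos[marker_idx],
        })
        locus_ids = np.array([f"m{j}" for j in marker_idx], dtype=object)
        return GenotypeMatrix(dose[:, marker_idx], locus_ids, ids, mp)

    return SimulatedDataset(
        training=_panel(train_dose, "train"),
        y=y,
        tbv=tbv,
        tau_group=tau_group,
        v_level=v_level,
        validation=_panel(valid_dose, "valid"),
        tbv_validation=tbv_valid,
        qtl_effects=a,
        sigma_a2=sigma_a2,
        sigma_e2_star=sigma_e2_star,
        v_true=v_true,
        sigma2_ei=sigma2_ei,
        qtl_idx=qtl_idx,
        marker_idx=marker_idx,
        scenario=scenario,
    )
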