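"""Model comparison, genomic prediction and MCMC diagnostics.

Conditional predictive ordinates (harmonic-mean estimator, computed in a
guarded log domain), pseudo-Bayes factors, genomic breeding values and
their accuracy, cluster-stratified k-fold cross-validation, extreme-rank
(top/bottom decile) Spearman analysis, HPD/coverage utilities and
ESS/Gelman-Rubin convergence checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import pearsonr, spearmanr

from hetwgp.datamodel import GenotypeMatrix, ModelSpec, TrainingData
from hetwgp.mcmc import McmcSpec, PosteriorSamples, fit

__all__ = [
    "CpoTable",
    "FoldAssignment",
    "cpo",
    "log10_pbf",
    "gebv",
    "prediction_accuracy",
    "stratified_kfold",
    "cv_predictive_ability",
    "spearman_extremes",
    "hpd_interval",
    "coverage",
    "diagnostics",
]


@dataclass
class CpoTable:
    """Per-observation conditional predictive ordinates for one model."""

    values: np.ndarray          # CPO_i > 0
    log10_sum: float            # sum_i log10 CPO_i


@dataclass
class FoldAssignment:
    """Cluster-stratified fold labels (1..k) for cross-validation."""

    fold: np.ndarray
    k: int
    strata: np.ndarray


def cpo(samples: PosteriorSamples) -> CpoTable:
    """Harmonic-mean CPO for every observation.

    ``CPO_i = (mean_b 1 / L(y_i | theta_b))**-1``; the mean of inverse
    likelihoods is evaluated with log-sum-exp to avoid overflow of the
    small-likelihood draws that dominate the harmonic mean.
    """
    ll = samples.loglik
    if not np.isfinite(ll).all():
        b, i = np.argwhere(~np.isfinite(ll))[0]
        raise FloatingPointError(
            f"non-finite log-likelihood at saved iteration {b}, observation {i}"
        )
    B = ll.shape[0]
    log_cpo = math.log(B) - logsumexp(-ll, axis=0)
    return CpoTable(np.exp(log_cpo), float(np.sum(log_cpo) / math.log(10.0)))


def log10_pbf(samples_ht: PosteriorSamples, samples_ho: PosteriorSamples) -> float:
    """log10 pseudo-Bayes factor of the heteroskedastic over the
    homoskedastic model; positive values favor the heteroskedastic fit."""
    if samples_ht.loglik.shape[1] != samples_ho.loglik.shape[1]:
        raise ValueError("models were fitted to different observation sets")
    return cpo(samples_ht).log10_sum - cpo(samples_ho).log10_sum


def gebv(samples: PosteriorSamples, genotypes: GenotypeMatrix,
         train_locus_ids: np.ndarray | None = None,
         include_polygenic: bool = False,
         individual_ids: np.ndarray | None = None) -> np.ndarray:
    """Genomic breeding values from posterior-mean marker effects.

    ``GEBV_i = sum_j z_ij ghat_j`` (plus ``uhat_i`` when
    ``include_polygenic``, in which case ``individual_ids`` must index the
    fitted polygenic vector order).  If ``train_locus_ids`` is given the
    evaluation panel must match it exactly.
    """
    g_hat = samples.mean("g")
    if train_locus_ids is not None and not np.array_equal(
            np.asarray(train_locus_ids), genotypes.locus_ids):
        raise ValueError("marker panel mismatch between training and "
                         "evaluation genotypes")
    if genotypes.p != len(g_hat):
        raise ValueError("genotype panel width differs from fitted markers")
    out = genotypes.dosages @ g_hat
    if include_polygenic:
        u_hat = samples.mean("u")
        if individual_ids is None:
            raise ValueError("individual_ids needed to add polygenic effects")
        out = out + u_hat[np.asarray(individual_ids)]
    return out


def prediction_accuracy(tbv: np.ndarray, gebv_: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, float)
    gebv_ = np.asarray(gebv_, float)
    if len(tbv) != len(gebv_) or len(tbv) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if tbv.std() == 0.0 or gebv_.std() == 0.0:
        raise ValueError("correlation undefined for constant input")
    return float(pearsonr(tbv, gebv_)[0])


def stratified_kfold(cluster_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random fold assignment balanced within every cluster.

    Within each cluster, members are shuffled and dealt cyclically from a
    random starting fold, so per-cluster fold counts differ by at most one
    and the folds partition the full index set.  Clusters smaller than k
    are simply absent from some folds (warned).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(cluster_ids)
    rng = np.random.default_rng(seed)
    fold = np.zeros(len(labels), dtype=np.int64)
    small = 0
    for lab in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == lab)
        if len(members) < k:
            small += 1
        perm = rng.permutation(members)
        start = rng.integers(k)
        fold[perm] = (start + np.arange(len(perm))) % k + 1
    if small:
        warnings.warn(f"{small} cluster(s) smaller than k={k}: absent from "
                      "some folds", stacklevel=2)
    return FoldAssignment(fold, k, labels)


def _subset_training(data: TrainingData, idx: np.ndarray) -> TrainingData:
    return TrainingData(
        y=data.y[idx],
        X=data.X[idx],
        W=None if data.W is None else data.W[idx],
        M=None if data.M is None else data.M[idx],
        cluster_ids=None if data.cluster_ids is None
        else np.asarray(data.cluster_ids)[idx],
        pedigree=data.pedigree,
        individual_ids=None if data.individual_ids is None
        else np.asarray(data.individual_ids)[idx],
    )


def cv_predictive_ability(data: TrainingData, genotypes: GenotypeMatrix,
                          spec: ModelSpec, mcmc: McmcSpec,
                          folds: FoldAssignment) -> pd.DataFrame:
    """Per-fold Pearson correlation between observed and predicted phenotypes.

    The model is refit on the training folds only; validation phenotypes
    never enter estimation.  Predictions combine posterior-mean fixed
    effects, marker effects, polygenic effects and mean-model cluster
    effects evaluated at the validation rows.
    """
    rows = []
    for f in range(1, folds.k + 1):
        val = np.flatnonzero(folds.fold == f)
        trn = np.flatnonzero(folds.fold != f)
        if len(val) < 3:
            warnings.warn(f"fold {f} has fewer than 3 validation animals; "
                          "skipped", stacklevel=2)
            continue
        sub = _subset_training(data, trn)
        gt_trn = GenotypeMatrix(genotypes.dosages[trn],
                                genotypes.locus_ids,
                                genotypes.individual_ids[trn])
        samples = fit(sub, gt_trn, spec, mcmc)
        yhat = data.X[val] @ samples.mean("beta")
        yhat += genotypes.dosages[val] @ samples.mean("g")
        if "u" in samples.samples and data.individual_ids is not None:
            # the polygenic vector spans the full pedigree, so validation
            # individuals carry estimated effects through their relatives
            pos = {pid: q for q, pid in
                   enumerate(data.pedigree["id"].to_numpy())}
            u_hat = samples.mean("u")
            ids = np.asarray(data.individual_ids)
            yhat += u_hat[[pos[i] for i in ids[val]]]
        if "d" in samples.samples and data.cluster_ids is not None:
            labels = np.asarray(data.cluster_ids)
            lvl = {lab: q for q, lab in
                   enumerate(sorted(set(labels[trn].tolist())))}
            d_hat = samples.mean("d")
            yhat += np.array([d_hat[lvl[lab]] if lab in lvl else 0.0
                              for lab in labels[val]])
        rows.append({"fold": f, "n_val": len(val),
                     "rho": prediction_accuracy(data.y[val], yhat)})
    return pd.DataFrame(rows)


def spearman_extremes(gebv_a: np.ndarray, gebv_b: np.ndarray,
                      fraction: float = 0.10):
    """Spearman rank correlation restricted to the extremes of ``gebv_a``.

    The top (bottom) set is the highest (lowest) ``fraction`` of
    individuals ranked by ``gebv_a``; ties at the boundary are resolved by
    stable index order.  Returns ``(rho_top, rho_bottom)``.
    """
    a = np.asarray(gebv_a, float)
    b = np.asarray(gebv_b, float)
    if len(a) != len(b):
        raise ValueError("GEBV vectors must cover the same individuals")
    m = int(round(len(a) * fraction))
    if m < 3:
        raise ValueError("extreme sets need at least 3 individuals")
    order = np.argsort(a, kind="stable")
    bottom = order[:m]
    top = order[-m:]
    rho_top = float(spearmanr(a[top], b[top])[0])
    rho_bottom = float(spearmanr(a[bottom], b[bottom])[0])
    return rho_top, rho_bottom


def hpd_interval(draws: np.ndarray, mass: float = 0.95):
    """Shortest contiguous interval containing ``mass`` of sorted draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def coverage(intervals, truth: float) -> float:
    """Fraction of (lower, upper) intervals containing the true value."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("need at least one interval")
    hits = sum(1 for lo, hi in intervals if lo <= truth <= hi)
    return hits / len(intervals)


def diagnostics(samples: PosteriorSamples, names=None,
                ess_min: float = 100.0, rhat_max: float = 1.2) -> pd.DataFrame:
    """ESS and Gelman-Rubin shrink factor per scalar hyperparameter.

    Flags follow the conventional thresholds (ESS > 100, shrink < 1.2);
    the shrink factor needs at least two chains and is NaN otherwise.
    Constant chains yield NaN ESS and are flagged.
    """
    import arviz as az

    if names is None:
        names = [k for k, val in samples.samples.items() if val.ndim == 1]
    rows = []
    for name in names:
        x = samples.by_chain(name)
        if x.ndim != 2:
            continue
        if np.allclose(x, x.flat[0]):
            rows.append({"parameter": name, "ess": np.nan, "rhat": np.nan,
                         "ok": False})
            continue
        ess = float(az.ess(az.convert_to_dataset(x))["x"])
        rhat = (float(az.rhat(az.convert_to_dataset(x))["x"])
                if samples.n_chains >= 2 else np.nan)
        ok = ess > ess_min and (np.isnan(rhat) or rhat < rhat_max)
        rows.append({"parameter": name, "ess": ess, "rhat": rhat, "ok": ok})
    return pd.DataFrame(rows)
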