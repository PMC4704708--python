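"""Gibbs/Metropolis samplers for whole-genome prediction models.

Fits the mean model ``y = X beta + Z (g o delta) + Z_u u + D d + e`` under
four marker-effect prior families (RR-BLUP, BayesA, BayesB, BayesCpi) and
either a common residual variance or the log-linear structural model
``ln sigma2_ei = w_i' ln tau + m_i' ln v`` with fixed multipliers ``tau``
(set-to-zero; component 0 is the baseline variance) and cluster relative
variances ``v_l ~ IG(alpha_v, alpha_v - 1)``.

All scalar variance updates use the conjugate scaled-inverse-chi-square
form implied by the improper reference prior ``(variance)**(-1/2)``
(uniform on the standard deviation), giving ``count - 1`` degrees of
freedom.  Parameters without conjugate conditionals (free tau components,
alpha_v, nu_g) use adaptive Gaussian random walks on a log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit
from scipy.special import gammaln

from hetwgp.datamodel import (
    GenotypeMatrix,
    ModelSpec,
    TrainingData,
    build_a_matrix,
)

__all__ = [
    "ParameterState",
    "McmcSpec",
    "PosteriorSamples",
    "residual_variance_of",
    "residual_variances",
    "update_fixed_effects",
    "update_residual_scale_homo",
    "update_v",
    "update_pi",
    "update_marker_variances_t",
    "update_s_g2",
    "mh_step_positive",
    "log_target_nu_g",
    "log_target_alpha_v",
    "fit",
]

_MH_TARGET_ACCEPT = 0.35  # middle of the 20-50% band
_ADAPT_WINDOW = 50


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ParameterState:
    """One full set of model unknowns (a single MCMC state)."""

    beta: np.ndarray
    g: np.ndarray
    delta: np.ndarray
    sigma_g2: float
    sigma_gj2: Optional[np.ndarray]
    nu_g: float
    s_g2: float
    pi: float
    sigma_e2: float
    tau: Optional[np.ndarray]
    v: Optional[np.ndarray]
    alpha_v: float
    u: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    sigma_d2: float = 0.0


@dataclass
class McmcSpec:
    """Chain-length and tuning configuration.

    ``n_iter`` counts saved (post burn-in, post thinning) iterations per
    chain.  Metropolis step sizes are adapted toward a 20-50% acceptance
    rate during burn-in and frozen afterwards.
    """

    n_burnin: int = 2000
    n_iter: int = 4000
    thin: int = 2
    n_chains: int = 1
    seed: int = 0
    step_tau: float = 0.3
    step_alpha_v: float = 0.6
    step_nu_g: float = 0.5

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("n_iter > 0, thin >= 1, n_chains >= 1 required")


class PosteriorSamples:
    """Thinned posterior draws plus per-observation Gaussian log-likelihoods.

    ``samples[name]`` has shape (n_chains * n_saved, ...); ``loglik`` has
    shape (n_chains * n_saved, n); ``chain`` labels each stored iteration.
    """

    def __init__(self, samples: dict, loglik: np.ndarray, chain: np.ndarray,
                 n_chains: int):
        self.samples = samples
        self.loglik = loglik
        self.chain = chain
        self.n_chains = n_chains

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[name]

    def mean(self, name: str) -> np.ndarray:
        return self.samples[name].mean(axis=0)

    def by_chain(self, name: str) -> np.ndarray:
        """Reshape a parameter to (n_chains, n_saved, ...)."""
        x = self.samples[name]
        per = x.shape[0] // self.n_chains
        return x.reshape(self.n_chains, per, *x.shape[1:])

    @property
    def n_saved(self) -> int:
        return self.loglik.shape[0]

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path, __loglik=self.loglik, __chain=self.chain,
            __n_chains=self.n_chains, **self.samples,
        )

    @classmethod
    def from_npz(cls, path) -> "PosteriorSamples":
        with np.load(path) as z:
            samples = {k: z[k] for k in z.files if not k.startswith("__")}
            return cls(samples, z["__loglik"], z["__chain"],
                       int(z["__n_chains"]))


# ---------------------------------------------------------------------------
# residual variance structure
# ---------------------------------------------------------------------------

def residual_variances(tau, v, W, m_idx=None) -> np.ndarray:
    """Vector of ``sigma2_ei = exp(W ln tau + ln v[level])``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0) or (v is not None and np.any(np.asarray(v) <= 0)):
        raise ValueError("tau and v must be strictly positive")
    log_s2 = W @ np.log(tau)
    if v is not None and m_idx is not None:
        log_s2 = log_s2 + np.log(np.asarray(v, dtype=float))[m_idx]
    return np.exp(log_s2)


def residual_variance_of(tau, v, w_row, m_row=None) -> float:
    """Single-observation residual variance under the log-linear model."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be strictly positive")
    out = float(np.exp(np.asarray(w_row, float) @ np.log(tau)))
    if m_row is not None and v is not None:
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("v must be strictly positive")
        out *= float(np.exp(np.asarray(m_row, float) @ np.log(v)))
    return out


# ---------------------------------------------------------------------------
# scalar conditional draws (exposed for oracle verification)
# ---------------------------------------------------------------------------

def update_fixed_effects(X, y_partial, omega, rng):
    """Draw beta from its Gaussian full conditional (weighted LS form)."""
    Xw = X * omega[:, None]
    A = X.T @ Xw
    b = Xw.T @ y_partial
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal-equations matrix in fixed-effect update"
        ) from err
    mean = np.linalg.solve(A, b)
    z = rng.standard_normal(X.shape[1])
    return mean + np.linalg.solve(L.T, z)


def update_residual_scale_homo(e, rng):
    """sigma_e2 | e ~ scaled-inv-chi2(n-1, sum(e^2)/(n-1))."""
    n = len(e)
    if n <= 1:
        raise ValueError("need at least two observations")
    return float(np.sum(np.square(e)) / rng.chisquare(n - 1))


def update_v(e, t_part, m_idx, n_levels, alpha_v, rng):
    """Conjugate inverted-gamma update of all cluster relative variances.

    ``t_part`` is ``exp(w_i' ln tau)`` per observation; clusters with no
    observations draw from the prior IG(alpha_v, alpha_v - 1).
    """
    resid2 = np.square(e) / t_part
    ssq = np.bincount(m_idx, weights=resid2, minlength=n_levels)
    n_l = np.bincount(m_idx, minlength=n_levels)
    shape = alpha_v + 0.5 * n_l
    rate = (alpha_v - 1.0) + 0.5 * ssq
    return rate / rng.gamma(shape)


def update_pi(delta, rng, a: float = 10.0, b: float = 1.0):
    """pi | delta ~ Beta(a + #null, b + #included); pi is P(marker null)."""
    n1 = int(np.sum(delta))
    n0 = len(delta) - n1
    return float(rng.beta(a + n0, b + n1))


def update_marker_variances_t(g, delta, nu_g, s_g2, rng):
    """Per-marker variance update under the Student-t (BayesA/B) prior.

    Included markers (delta=1) draw from the conjugate
    scaled-inverse-chi-square(nu_g + 1, (nu_g s_g2 + g_j^2)/(nu_g + 1));
    excluded markers refresh from the chi^-2(nu_g, nu_g s_g2) prior.
    """
    incl = np.asarray(delta) == 1
    scale = nu_g * s_g2 + np.where(incl, np.square(g), 0.0)
    df = np.where(incl, nu_g + 1.0, nu_g)
    return scale / rng.chisquare(df)


def update_s_g2(sigma_gj2, nu_g, rng):
    """Gamma-form conditional of the Student-t scale given marker variances."""
    m = len(sigma_gj2)
    shape = 0.5 * m * nu_g + 0.5
    rate = 0.5 * nu_g * np.sum(1.0 / sigma_gj2)
    return float(rng.gamma(shape) / rate)


def mh_step_positive(x, log_density: Callable[[float], float], step, rng,
                     lower: float = 0.0):
    """One Gaussian random-walk Metropolis step on ``ln(x - lower)``.

    ``log_density`` is the (unnormalized) log target in x-space; the
    Jacobian of the transform is included in the acceptance ratio.
    Returns ``(new_x, accepted)``.
    """
    w = math.log(x - lower)
    w_new = w + step * rng.standard_normal()
    x_new = lower + math.exp(w_new)
    log_acc = (log_density(x_new) + w_new) - (log_density(x) + w)
    if math.log(rng.random()) < log_acc:
        return x_new, True
    return x, False


def log_target_nu_g(nu, sigma_gj2, s_g2):
    """Log full conditional of the Student-t df given marker variances."""
    if nu <= 0:
        return -np.inf
    half = 0.5 * nu
    ll = np.sum(
        half * math.log(half * s_g2)
        - gammaln(half)
        - (half + 1.0) * np.log(sigma_gj2)
        - half * s_g2 / sigma_gj2
    )
    return float(ll - 2.0 * math.log1p(nu))


def log_target_alpha_v(av, v):
    """Log full conditional of the inverted-gamma shape given v draws."""
    if av <= 2.0:
        return -np.inf
    b = av - 1.0
    ll = np.sum(av * math.log(b) - gammaln(av) - (av + 1.0) * np.log(v) - b / v)
    return float(ll - 2.0 * math.log1p(av))


def log_target_tau_component(t, e_members, base_members):
    """Log conditional of one free tau multiplier given member residuals.

    ``base_members`` is sigma2_ei / tau_k for the member observations; the
    reference prior contributes ``-(1/2) ln tau``.
    """
    if t <= 0:
        return -np.inf
    s = np.sum(np.square(e_members) / base_members)
    n_k = len(e_members)
    return float(-0.5 * (n_k + 1.0) * math.log(t) - 0.5 * s / t)


# ---------------------------------------------------------------------------
# numba marker-scan kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_normal(Zt, e, omega, g, lam, zdraws):  # pragma: no cover
    p, n = Zt.shape
    for j in range(p):
        szz = 0.0
        sze = 0.0
        for i in range(n):
            w = omega[i] * Zt[j, i]
            szz += w * Zt[j, i]
            sze += w * e[i]
        C = szz + lam[j]
        mean = (sze + g[j] * szz) / C
        gn = mean + zdraws[j] / math.sqrt(C)
        diff = gn - g[j]
        if diff != 0.0:
            for i in range(n):
                e[i] -= Zt[j, i] * diff
        g[j] = gn


@njit(cache=True)
def _scan_mixture(Zt, e, omega, g, delta, lam, log_prior_odds, zdraws,
                  udraws):  # pragma: no cover
    p, n = Zt.shape
    for j in range(p):
        szz = 0.0
        sze = 0.0
        for i in range(n):
            w = omega[i] * Zt[j, i]
            szz += w * Zt[j, i]
            sze += w * e[i]
        C = szz + lam[j]
        rhs = sze + g[j] * szz
        # marker effect integrated out of the two-component posterior
        logbf = 0.5 * (math.log(lam[j]) - math.log(C)) + 0.5 * rhs * rhs / C
        logit = log_prior_odds + logbf
        if logit > 35.0:
            p1 = 1.0
        elif logit < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + math.exp(-logit))
        gold = g[j]
        if udraws[j] < p1:
            gn = rhs / C + zdraws[j] / math.sqrt(C)
            delta[j] = 1
        else:
            gn = 0.0
            delta[j] = 0
        diff = gn - gold
        if diff != 0.0:
            for i in range(n):
                e[i] -= Zt[j, i] * diff
        g[j] = gn


# ---------------------------------------------------------------------------
# adaptive step helper
# ---------------------------------------------------------------------------

class _AdaptiveStep:
    def __init__(self, step: float):
        self.step = step
        self._accepts = 0
        self._tries = 0
        self.frozen = False

    def record(self, accepted: bool) -> None:
        if self.frozen:
            return
        self._tries += 1
        self._accepts += int(accepted)
        if self._tries >= _ADAPT_WINDOW:
            rate = self._accepts / self._tries
            self.step *= math.exp(0.5 * (rate - _MH_TARGET_ACCEPT))
            self._accepts = 0
            self._tries = 0


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Chain:
    """One MCMC chain; systematic-scan Gibbs with Metropolis sub-steps."""

    def __init__(self, data: TrainingData, genotypes: GenotypeMatrix,
                 spec: ModelSpec, mcmc: McmcSpec, rng: np.random.Generator,
                 disperse: float = 0.0):
        self.rng = rng
        self.spec = spec
        self.mcmc = mcmc
        self.y = data.y
        self.X = data.X
        self.n = len(self.y)
        self.Zt = np.ascontiguousarray(genotypes.dosages.T, dtype=np.float64)
        self.p = self.Zt.shape[0]
        if np.any(self.Zt.std(axis=1) == 0.0):
            warnings.warn("zero-variance marker column(s): effect sampled "
                          "from prior only", stacklevel=2)
        var_y = float(np.var(self.y))
        self.eps = 1e-12 * max(var_y, 1e-30)
        self.het = spec.heteroskedastic
        fixed = dict(spec.fixed_hyperparams)

        # variance-model designs
        if self.het:
            self.W = data.W if data.W is not None else np.ones((self.n, 1))
            if data.M is not None:
                self.M = data.M
                self.m_idx = np.argmax(data.M, axis=1)
                self.t_levels = data.M.shape[1]
            else:
                self.M = None
                self.m_idx = None
                self.t_levels = 0
            self.tau_members = [np.flatnonzero(self.W[:, k] != 0)
                                for k in range(1, self.W.shape[1])]
        else:
            self.W = None

        # mean-model clusters
        if data.cluster_ids is not None:
            labels = np.asarray(data.cluster_ids)
            self.d_levels = sorted(set(labels.tolist()))
            lvl = {lab: k for k, lab in enumerate(self.d_levels)}
            self.d_idx = np.array([lvl[lab] for lab in labels])
            self.n_d = len(self.d_levels)
        else:
            self.d_idx = None
            self.n_d = 0

        # polygenic effects
        self.use_u = data.pedigree is not None and "sigma_u2" in fixed
        if self.use_u:
            am = build_a_matrix(data.pedigree)
            self.A_inv = np.linalg.inv(am.values)
            if data.individual_ids is None:
                raise ValueError("individual_ids required for polygenic fit")
            pos = {pid: k for k, pid in enumerate(am.ids)}
            self.u_idx = np.array([pos[i] for i in data.individual_ids])
            self.n_u = am.values.shape[0]
            self.sigma_u2 = float(fixed["sigma_u2"])

        # initial state
        disp = math.exp(disperse * rng.standard_normal()) if disperse else 1.0
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        sum_var_z = float(np.sum(self.Zt.var(axis=1))) or 1.0
        sg0 = 0.5 * var_y / sum_var_z * disp
        nu0 = float(fixed.get("nu_g", 4.0 * disp))
        self.state = ParameterState(
            beta=beta0,
            g=np.zeros(self.p),
            delta=np.ones(self.p, dtype=np.int64),
            sigma_g2=float(fixed.get("sigma_g2", sg0)),
            sigma_gj2=np.full(self.p, sg0),
            nu_g=max(nu0, 2.1),
            s_g2=float(fixed.get("s_g2", sg0 * max(nu0 - 2.0, 0.5) / nu0)),
            pi=float(fixed.get("pi", 0.9)),
            sigma_e2=0.5 * var_y * disp,
            tau=None,
            v=None,
            alpha_v=10.0 * disp,
            sigma_d2=0.1 * var_y * disp,
        )
        if self.het:
            self.state.tau = np.ones(self.W.shape[1])
            self.state.tau[0] = 0.5 * var_y * disp
            if self.t_levels:
                self.state.v = np.ones(self.t_levels)
            self.state.alpha_v = max(2.5, 10.0 * disp)
        if self.d_idx is not None:
            self.state.d = np.zeros(self.n_d)
        if self.use_u:
            self.state.u = np.zeros(self.n_u)

        self.fixed = fixed
        self.e = self.y - self.X @ self.state.beta
        self._sync_sigma2()
        self.steps = {
            "tau": _AdaptiveStep(mcmc.step_tau),
            "alpha_v": _AdaptiveStep(mcmc.step_alpha_v),
            "nu_g": _AdaptiveStep(mcmc.step_nu_g),
        }

    # -- residual variance bookkeeping ----------------------------------
    def _sync_sigma2(self) -> None:
        st = self.state
        if self.het:
            self.t_part = np.exp(self.W @ np.log(st.tau))
            self.sigma2 = self.t_part.copy()
            if st.v is not None:
                self.sigma2 *= st.v[self.m_idx]
        else:
            self.t_part = None
            self.sigma2 = np.full(self.n, st.sigma_e2)
        self.omega = 1.0 / self.sigma2

    # -- one full Gibbs scan --------------------------------------------
    def scan(self) -> None:
        st, rng = self.state, self.rng
        # fixed effects
        r = self.e + self.X @ st.beta
        st.beta = update_fixed_effects(self.X, r, self.omega, rng)
        self.e = r - self.X @ st.beta

        # marker effects
        family = self.spec.marker_prior
        if family in ("rrblup", "bayesa"):
            lam = (np.full(self.p, 1.0 / st.sigma_g2) if family == "rrblup"
                   else 1.0 / st.sigma_gj2)
            _scan_normal(self.Zt, self.e, self.omega, st.g, lam,
                         rng.standard_normal(self.p))
            st.delta[:] = 1
        else:
            lam = (1.0 / st.sigma_gj2 if family == "bayesb"
                   else np.full(self.p, 1.0 / st.sigma_g2))
            lpo = math.log(1.0 - st.pi) - math.log(st.pi)
            _scan_mixture(self.Zt, self.e, self.omega, st.g, st.delta, lam,
                          lpo, rng.standard_normal(self.p), rng.random(self.p))

        # marker variances
        if family in ("rrblup", "bayescpi") and "sigma_g2" in self.fixed:
            pass
        elif family == "rrblup":
            st.sigma_g2 = self._inv_chi2(st.g, self.p)
        elif family == "bayescpi":
            inc = st.delta == 1
            st.sigma_g2 = self._inv_chi2(st.g[inc], int(inc.sum()))
        else:  # bayesa / bayesb
            st.sigma_gj2 = update_marker_variances_t(st.g, st.delta,
                                                     st.nu_g, st.s_g2, rng)

        # pi and Student-t hyperparameters
        if family in ("bayesb", "bayescpi") and "pi" not in self.fixed:
            a, b = self.spec.pi_prior
            st.pi = update_pi(st.delta, rng, a, b)
        if family in ("bayesa", "bayesb"):
            if "s_g2" not in self.fixed:
                st.s_g2 = update_s_g2(st.sigma_gj2, st.nu_g, rng)
            if "nu_g" not in self.fixed:
                st.nu_g, acc = mh_step_positive(
                    st.nu_g,
                    lambda nu: log_target_nu_g(nu, st.sigma_gj2, st.s_g2),
                    self.steps["nu_g"].step, rng)
                self.steps["nu_g"].record(acc)

        # polygenic effects
        if self.use_u:
            r = self.e + st.u[self.u_idx]
            wsum = np.bincount(self.u_idx, weights=self.omega,
                               minlength=self.n_u)
            rhs = np.bincount(self.u_idx, weights=self.omega * r,
                              minlength=self.n_u)
            C = self.A_inv / self.sigma_u2
            C[np.diag_indices_from(C)] += wsum
            L = np.linalg.cholesky(C)
            mean = np.linalg.solve(C, rhs)
            st.u = mean + np.linalg.solve(L.T, rng.standard_normal(self.n_u))
            self.e = r - st.u[self.u_idx]

        # mean-model cluster effects
        if self.d_idx is not None:
            r = self.e + st.d[self.d_idx]
            wsum = np.bincount(self.d_idx, weights=self.omega,
                               minlength=self.n_d)
            rhs = np.bincount(self.d_idx, weights=self.omega * r,
                              minlength=self.n_d)
            C = wsum + 1.0 / st.sigma_d2
            st.d = rhs / C + rng.standard_normal(self.n_d) / np.sqrt(C)
            self.e = r - st.d[self.d_idx]
            st.sigma_d2 = self._inv_chi2(st.d, self.n_d)

        # residual-variance structure
        if self.het:
            self._update_tau()
            if st.v is not None:
                st.v = update_v(self.e, self.t_part, self.m_idx,
                                self.t_levels, st.alpha_v, rng)
                self._sync_sigma2()
                st.alpha_v, acc = mh_step_positive(
                    st.alpha_v,
                    lambda av: log_target_alpha_v(av, st.v),
                    self.steps["alpha_v"].step, rng, lower=2.0)
                self.steps["alpha_v"].record(acc)
        else:
            st.sigma_e2 = update_residual_scale_homo(self.e, rng)
            self._sync_sigma2()

    def _update_tau(self) -> None:
        st, rng = self.state, self.rng
        # baseline: conjugate given the multiplicative remainder
        c = self.sigma2 / st.tau[0]
        ssq = float(np.sum(np.square(self.e) / c))
        st.tau[0] = ssq / rng.chisquare(self.n - 1)
        self._sync_sigma2()
        # free components: random-walk Metropolis on the log scale
        for k, members in enumerate(self.tau_members, start=1):
            base = self.sigma2[members] / st.tau[k]
            e_m = self.e[members]
            new, acc = mh_step_positive(
                st.tau[k],
                lambda t: log_target_tau_component(t, e_m, base),
                self.steps["tau"].step, rng)
            self.steps["tau"].record(acc)
            if acc:
                st.tau[k] = new
                self._sync_sigma2()

    def _inv_chi2(self, values, count) -> float:
        df = max(count - 1, 1)
        ssq = max(float(np.sum(np.square(values))), self.eps)
        return float(ssq / self.rng.chisquare(df))

    def loglik(self) -> np.ndarray:
        return -0.5 * (np.log(2.0 * np.pi * self.sigma2)
                       + np.square(self.e) / self.sigma2)

    def check_finite(self, iteration: int) -> None:
        if not (np.isfinite(self.e).all()
                and np.isfinite(self.sigma2).all()):
            raise FloatingPointError(
                f"divergent sampler state at iteration {iteration}"
            )


def fit(data: TrainingData, genotypes: GenotypeMatrix, spec: ModelSpec,
        mcmc: McmcSpec) -> PosteriorSamples:
    """Run the Gibbs sampler and collect thinned posterior draws.

    Chains beyond the first start from hyperparameter values dispersed by a
    small multiplicative factor (kept inside the parameter space).  The
    returned container holds per-iteration draws of every model unknown and
    the per-observation Gaussian log-likelihoods needed for conditional
    predictive ordinates.
    """
    if len(data.y) != genotypes.n:
        raise ValueError("phenotype and genotype row counts differ")
    if spec.heteroskedastic and data.W is None and data.M is None:
        warnings.warn("heteroskedastic fit without W or M reduces to the "
                      "homoskedastic model", stacklevel=2)
    collected: dict[str, list] = {}
    logliks = []
    chain_labels = []
    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.n_chains)
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        chain = _Chain(data, genotypes, spec, mcmc, rng,
                       disperse=0.05 if c else 0.0)
        for it in range(mcmc.n_burnin):
            chain.scan()
        chain.check_finite(mcmc.n_burnin)
        for s in chain.steps.values():
            s.frozen = True
        for b in range(mcmc.n_iter):
            for _ in range(mcmc.thin):
                chain.scan()
            st = chain.state
            family = spec.marker_prior
            row = {"beta": st.beta.copy(), "g": st.g.copy()}
            if family in ("rrblup", "bayescpi"):
                row["sigma_g2"] = st.sigma_g2
            if family in ("bayesb", "bayescpi"):
                row["delta"] = st.delta.copy()
                row["pi"] = st.pi
            if family in ("bayesa", "bayesb"):
                row["nu_g"] = st.nu_g
                row["s_g2"] = st.s_g2
            if spec.heteroskedastic:
                row["tau"] = st.tau.copy()
                row["alpha_v"] = st.alpha_v
                if st.v is not None:
                    row["v"] = st.v.copy()
            else:
                row["sigma_e2"] = st.sigma_e2
            if st.u is not None:
                row["u"] = st.u.copy()
            if st.d is not None:
                row["d"] = st.d.copy()
                row["sigma_d2"] = st.sigma_d2
            for k, val in row.items():
                collected.setdefault(k, []).append(val)
            logliks.append(chain.loglik())
            chain_labels.append(c)
        chain.check_finite(mcmc.n_burnin + mcmc.n_iter * mcmc.thin)
    samples = {k: np.asarray(v) for k, v in collected.items()}
    return PosteriorSamples(samples, np.asarray(logliks),
                            np.asarray(chain_labels), mcmc.n_chains)
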