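"""Poisson/binomial first-difference (random-walk) models for incidence.

For evenly spaced periods t = 1..n, observed case counts y_t and
populations at risk P_t, the Poisson model is

    y_t ~ Poisson(P_t * exp(eta_t))
    eta_t ~ Normal(eta_{t-1}, tau^2),  t > 1
    eta_1 ~ Normal(-5, 5^2)
    tau ~ HalfNormal(1)

with eta the latent log-rate.  The binomial variant replaces the
likelihood with y_t ~ Binomial(P_t, inverse_logit(eta_t)) and puts the
random walk on the logit scale.  The prior on eta_1 is centered on a rate
of e^-5 (about 674 per 100,000) and is diffuse for rare events; the
half-normal scale prior reflects that log-rates drift slowly.

The joint variant couples k groups through multivariate-normal increments
eta_t ~ Normal(eta_{t-1}, Sigma) with Sigma = diag(tau) Corr diag(tau) and
an LKJ prior on Corr, so related series can share trend information.

Fitting uses the package's Hamiltonian Monte Carlo sampler on a
non-centered parameterization (standardized increments z, log tau), which
removes the funnel geometry that the centered random walk induces when tau
is small.  Correlation parameters of the joint model are updated by an
adaptive Metropolis step within the HMC loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import expit

from . import _hmc, _lkj
from .diagnostics import ConvergenceWarning, DiagnosticsReport, diagnose
from .io import CaseSeries

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "ConvergenceError",
    "log_prior_density",
    "log_likelihood",
    "fit",
]


class ConvergenceError(RuntimeError):
    """Sampling failed badly (e.g. excessive divergent transitions)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class ModelSpec:
    """Model family, priors, and sampler settings.

    Defaults follow the package's reference analysis protocol: 4 chains of
    6000 draws each with the first 3000 discarded as warmup.
    """

    family: Literal["poisson", "binomial"] = "poisson"
    eta1_prior_mean: float = -5.0
    eta1_prior_sd: float = 5.0
    tau_prior_sd: float = 1.0
    joint: bool = False
    lkj_shape: float = 2.0
    chains: int = 4
    draws_per_chain: int = 6000
    warmup: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("poisson", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.eta1_prior_sd <= 0 or self.tau_prior_sd <= 0:
            raise ValueError("prior scales must be positive")
        if self.lkj_shape <= 0:
            raise ValueError("lkj_shape must be positive")
        if self.chains < 1 or self.draws_per_chain < 1:
            raise ValueError("chains and draws_per_chain must be positive")
        if not 0 <= self.warmup < self.draws_per_chain:
            raise ValueError("need 0 <= warmup < draws_per_chain")

    @property
    def retained(self) -> int:
        return self.draws_per_chain - self.warmup


@dataclass
class PosteriorDraws:
    """Posterior samples from :func:`fit`.

    ``eta`` is on the log (Poisson) or logit (binomial) scale, indexed
    ``(chain, draw, time, group, stratum)``; ``tau`` is the random-walk
    increment scale per series, ``(chain, draw, group, stratum)``.  For
    joint fits ``corr`` holds the increment correlation matrices,
    ``(chain, draw, stratum, k, k)``.
    """

    eta: np.ndarray
    tau: np.ndarray
    corr: np.ndarray | None
    spec: ModelSpec
    series: CaseSeries
    diagnostics: DiagnosticsReport | None = None

    @property
    def n_chains(self) -> int:
        return self.eta.shape[0]

    @property
    def n_retained(self) -> int:
        return self.eta.shape[1]

    def rate_draws(self, group=None, stratum=None, per: float = 1.0) -> np.ndarray:
        """Risk draws on the rate scale, ``(chain, draw, time)``.

        exp(eta) for Poisson fits, inverse-logit(eta) for binomial.
        """
        j = 0 if group is None else self.series.group_index(group)
        s = 0 if stratum is None else self.series.stratum_index(stratum)
        eta = self.eta[:, :, :, j, s]
        link = np.exp if self.spec.family == "poisson" else expit
        return per * link(eta)

    def stratum_rate_draws(self, group=None, per: float = 1.0) -> np.ndarray:
        """Rate draws for every stratum of one group, ``(chain, draw, time,
        stratum)``."""
        j = 0 if group is None else self.series.group_index(group)
        eta = self.eta[:, :, :, j, :]
        link = np.exp if self.spec.family == "poisson" else expit
        return per * link(eta)


# ---------------------------------------------------------------------------
# densities (reference implementations; the sampler uses its own fused
# gradient code, tested against these)

def log_prior_density(eta_path, tau: float, spec: ModelSpec) -> float:
    """Joint log prior of one latent path and its increment scale.

    ``log N(eta_1 | m0, s0^2) + sum_t log N(eta_t | eta_{t-1}, tau^2)
    + log HalfNormal(tau | tau_prior_sd)``.
    """
    eta = np.asarray(eta_path, dtype=float)
    if eta.ndim != 1 or eta.size < 1:
        raise ValueError("eta_path must be a 1-D sequence of length >= 1")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    lp = stats.norm.logpdf(eta[0], spec.eta1_prior_mean, spec.eta1_prior_sd)
    if eta.size > 1:
        lp += stats.norm.logpdf(np.diff(eta), 0.0, tau).sum()
    lp += stats.halfnorm.logpdf(tau, scale=spec.tau_prior_sd)
    return float(lp)


def log_likelihood(counts, populations, eta_path,
                   family: str = "poisson") -> float:
    """Log likelihood of one series under the chosen observation family."""
    y = np.asarray(counts, dtype=float)
    p = np.asarray(populations, dtype=float)
    eta = np.asarray(eta_path, dtype=float)
    if not (y.shape == p.shape == eta.shape):
        raise ValueError("counts, populations and eta_path must align")
    if family == "poisson":
        return float(stats.poisson.logpmf(y, p * np.exp(eta)).sum())
    if family == "binomial":
        if np.any(y > p):
            raise ValueError("binomial family requires y_t <= P_t")
        if np.any(p != np.floor(p)):
            raise ValueError("binomial family requires integral populations")
        return float(stats.binom.logpmf(y, p, expit(eta)).sum())
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# fused log-density + gradient kernels for the sampler

def _obs_terms(y, p, eta, family):
    """Pointwise log-likelihood (up to data-only constants) and its
    gradient in eta."""
    if family == "poisson":
        mu = p * np.exp(eta)
        ll = y * eta - mu
        return ll, y - mu
    prob = expit(eta)
    ll = y * eta - p * np.logaddexp(0.0, eta)
    return ll, y - p * prob


def _make_target_independent(y, p, spec):
    """Batched target for independent series.

    Positions are (B, n + 1): n standardized increments z then log tau.
    y, p have shape (B, n).
    """
    m0, s0 = spec.eta1_prior_mean, spec.eta1_prior_sd
    sig_tau = spec.tau_prior_sd
    n = y.shape[1]
    family = spec.family

    def logp_and_grad(q):
        z = q[:, :n]
        lt = np.clip(q[:, n], -40.0, 40.0)
        tau = np.exp(lt)
        steps = np.empty_like(z)
        steps[:, 0] = s0
        steps[:, 1:] = tau[:, None]
        w = steps * z
        eta = m0 + np.cumsum(w, axis=1)
        ll, g = _obs_terms(y, p, eta, family)
        G = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
        grad = np.empty_like(q)
        grad[:, :n] = steps * G - z
        grad[:, n] = (w[:, 1:] * G[:, 1:]).sum(axis=1) + 1.0 \
            - (tau / sig_tau) ** 2
        logp = ll.sum(axis=1) - 0.5 * (z * z).sum(axis=1) \
            - 0.5 * (tau / sig_tau) ** 2 + lt
        return logp, grad

    return logp_and_grad


def _make_target_joint(y, p, spec, k):
    """Batched target for one stratum of the joint (correlated) model.

    Positions are (B, n*k + k + k(k-1)/2): standardized increments z
    (time-major), log tau per group, then unconstrained correlation
    parameters u.  y, p have shape (B, n, k).
    """
    m0, s0 = spec.eta1_prior_mean, spec.eta1_prior_sd
    sig_tau = spec.tau_prior_sd
    n = y.shape[1]
    nu = _lkj.n_free(k)
    family = spec.family

    def unpack(q):
        z = q[:, : n * k].reshape(-1, n, k)
        lt = np.clip(q[:, n * k: n * k + k], -40.0, 40.0)
        u = q[:, n * k + k:]
        return z, lt, u

    def eta_of(z, tau, L):
        A = tau[:, :, None] * L  # rows scaled: (D L)
        w = np.empty_like(z)
        w[:, 0, :] = s0 * z[:, 0, :]
        w[:, 1:, :] = np.einsum("bjc,btc->btj", A, z[:, 1:, :])
        return m0 + np.cumsum(w, axis=1), A, w

    def logp_and_grad(q):
        z, lt, u = unpack(q)
        tau = np.exp(lt)
        L = _lkj.build_cholesky(u, k)
        eta, A, w = eta_of(z, tau, L)
        ll, g = _obs_terms(y, p, eta, family)
        G = np.cumsum(g[:, ::-1, :], axis=1)[:, ::-1, :]
        grad = np.empty_like(q)
        gz = np.empty_like(z)
        gz[:, 0, :] = s0 * G[:, 0, :] - z[:, 0, :]
        gz[:, 1:, :] = np.einsum("bjc,btj->btc", A, G[:, 1:, :]) \
            - z[:, 1:, :]
        grad[:, : n * k] = gz.reshape(len(q), -1)
        grad[:, n * k: n * k + k] = (w[:, 1:, :] * G[:, 1:, :]).sum(axis=1) \
            + 1.0 - (tau / sig_tau) ** 2
        grad[:, n * k + k:] = 0.0  # u moves via the Metropolis step only
        logp = ll.sum(axis=(1, 2)) - 0.5 * (z * z).sum(axis=(1, 2)) \
            - 0.5 * ((tau / sig_tau) ** 2).sum(axis=1) + lt.sum(axis=1) \
            + _lkj.log_cpc_prior(u, k, spec.lkj_shape)
        return logp, grad

    def make_gibbs(rng_unused=None):
        # adaptive random-walk Metropolis on u, Robbins-Monro scale tuning
        state = {"scale": None, "count": 0}

        def gibbs(q, rng, warm):
            z, lt, u = unpack(q)
            tau = np.exp(lt)
            if state["scale"] is None:
                state["scale"] = np.full(len(q), 0.5)
            scale = state["scale"]

            def cond_logp(u_):
                L = _lkj.build_cholesky(u_, k)
                eta, _, _ = eta_of(z, tau, L)
                ll, _ = _obs_terms(y, p, eta, family)
                return ll.sum(axis=(1, 2)) + _lkj.log_cpc_prior(
                    u_, k, spec.lkj_shape
                )

            lp0 = cond_logp(u)
            prop = u + scale[:, None] * rng.standard_normal(u.shape)
            lp1 = cond_logp(prop)
            acc_prob = np.exp(np.minimum(lp1 - lp0, 0.0))
            accept = rng.random(len(q)) < acc_prob
            u_new = np.where(accept[:, None], prop, u)
            if warm:
                state["count"] += 1
                gain = 2.0 / max(state["count"] ** 0.6, 1.0)
                target = 0.3 if nu > 1 else 0.44
                state["scale"] = np.clip(
                    scale * np.exp(gain * (acc_prob - target)), 1e-3, 5.0
                )
            q = q.copy()
            q[:, n * k + k:] = u_new
            return q

        return gibbs

    return logp_and_grad, make_gibbs


# ---------------------------------------------------------------------------
# fitting

def _empirical_eta0(y, p, family):
    """Shrunk empirical first-period log/logit rate used to start chains."""
    rate0 = (y[..., 0, :] + 0.5) / (p[..., 0, :] + 1.0) if y.ndim == 3 \
        else (y[..., 0] + 0.5) / (p[..., 0] + 1.0)
    if family == "poisson":
        return np.log(rate0)
    return np.log(rate0) - np.log1p(-np.minimum(rate0, 1 - 1e-9))


def fit(series: CaseSeries, spec: ModelSpec | None = None,
        check_diagnostics: bool = True,
        max_leapfrog: int | None = None) -> PosteriorDraws:
    """Fit the random-walk model to every series in a panel by MCMC.

    With ``spec.joint=False`` each (group, stratum) cell is modeled as an
    independent series with its own tau; with ``spec.joint=True`` the k
    groups within each stratum share multivariate-normal increments with
    covariance diag(tau) Corr diag(tau) and an LKJ(lkj_shape) prior on
    Corr.  All chains and independent series are advanced in one
    vectorized sampler pass.

    A :class:`ConvergenceWarning` (with the diagnostics attached to the
    returned object) is emitted when any monitored parameter fails the
    R-hat or MCSE gates; a :class:`ConvergenceError` is raised when more
    than 10% of post-warmup transitions diverge.
    """
    if spec is None:
        spec = ModelSpec()
    if max_leapfrog is None:
        # the coupled system needs longer trajectories to turn over tau
        max_leapfrog = 48 if spec.joint else 24
    if spec.family == "binomial":
        if np.any(series.counts > series.populations):
            raise ValueError("binomial family requires y_t <= P_t")
        if np.any(series.populations != np.floor(series.populations)):
            raise ValueError("binomial family requires integral populations")
    n, k, m = series.counts.shape
    if spec.joint and k < 2:
        raise ValueError("joint=True requires at least 2 groups")
    C = spec.chains
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(C)]

    if not spec.joint:
        # batch = (series-major, chain-minor)
        y2 = np.transpose(series.counts, (1, 2, 0)).reshape(k * m, n)
        p2 = np.transpose(series.populations, (1, 2, 0)).reshape(k * m, n)
        y_b = np.repeat(y2, C, axis=0).astype(float)
        p_b = np.repeat(p2, C, axis=0)
        dim = n + 1
        target = _make_target_independent(y_b, p_b, spec)
        B = y_b.shape[0]
        q0 = np.empty((B, dim))
        # per-chain jitter streams keep chain starts reproducible
        for b in range(B):
            q0[b] = 0.1 * chain_rngs[b % C].standard_normal(dim)
        eta0 = _empirical_eta0(y_b, p_b, spec.family)
        q0[:, 0] += (eta0 - spec.eta1_prior_mean) / spec.eta1_prior_sd
        q0[:, n] += np.log(0.05)
        res = _hmc.sample(
            target, q0, spec.draws_per_chain, spec.warmup, rng,
            max_leapfrog=max_leapfrog,
        )
        draws = res.draws  # (T, B, dim)
        T = res.n_kept
        z = draws[:, :, :n]
        lt = draws[:, :, n]
        tau_b = np.exp(lt)  # (T, B)
        steps = np.empty_like(z)
        steps[:, :, 0] = spec.eta1_prior_sd
        steps[:, :, 1:] = tau_b[:, :, None]
        eta_b = spec.eta1_prior_mean + np.cumsum(steps * z, axis=2)
        # unstack batch -> (chain, T, n, k, m)
        eta = np.empty((C, T, n, k, m))
        tau = np.empty((C, T, k, m))
        for s_idx in range(k * m):
            j, st = divmod(s_idx, m)
            for c in range(C):
                b = s_idx * C + c
                eta[c, :, :, j, st] = eta_b[:, b, :]
                tau[c, :, j, st] = tau_b[:, b]
        corr = None
        divergences = res.divergences
    else:
        # one joint system per stratum; batch = (stratum-major, chain-minor)
        nu = _lkj.n_free(k)
        dim = n * k + k + nu
        y3 = np.transpose(series.counts, (2, 0, 1)).astype(float)  # (m, n, k)
        p3 = np.transpose(series.populations, (2, 0, 1))
        y_b = np.repeat(y3, C, axis=0)
        p_b = np.repeat(p3, C, axis=0)
        target, make_gibbs = _make_target_joint(y_b, p_b, spec, k)
        B = y_b.shape[0]
        q0 = np.empty((B, dim))
        for b in range(B):
            q0[b] = 0.1 * chain_rngs[b % C].standard_normal(dim)
        eta0 = _empirical_eta0(y_b, p_b, spec.family)
        q0[:, :k] += (eta0 - spec.eta1_prior_mean) / spec.eta1_prior_sd
        q0[:, n * k: n * k + k] += np.log(0.05)
        frozen = np.zeros(dim, dtype=bool)
        frozen[n * k + k:] = True
        res = _hmc.sample(
            target, q0, spec.draws_per_chain, spec.warmup, rng,
            max_leapfrog=max_leapfrog, gibbs_step=make_gibbs(),
            frozen_mask=frozen,
        )
        draws = res.draws
        T = res.n_kept
        z = draws[:, :, : n * k].reshape(T, B, n, k)
        lt = draws[:, :, n * k: n * k + k]
        u = draws[:, :, n * k + k:]
        tau_b = np.exp(lt)  # (T, B, k)
        L = _lkj.build_cholesky(u, k)  # (T, B, k, k)
        A = tau_b[..., None] * L
        w = np.empty_like(z)
        w[:, :, 0, :] = spec.eta1_prior_sd * z[:, :, 0, :]
        w[:, :, 1:, :] = np.einsum("tbjc,tbsc->tbsj", A, z[:, :, 1:, :])
        eta_b = spec.eta1_prior_mean + np.cumsum(w, axis=2)  # (T, B, n, k)
        corr_b = _lkj.chol_to_corr(L)
        eta = np.empty((C, T, n, k, m))
        tau = np.empty((C, T, k, m))
        corr = np.empty((C, T, m, k, k))
        for st in range(m):
            for c in range(C):
                b = st * C + c
                eta[c, :, :, :, st] = eta_b[:, b]
                tau[c, :, :, st] = tau_b[:, b]
                corr[c, :, st] = corr_b[:, b]
        divergences = res.divergences

    div_frac = divergences.sum() / (divergences.size * max(res.n_kept, 1))
    out = PosteriorDraws(eta=eta, tau=tau, corr=corr, spec=spec,
                         series=series)
    if div_frac > 0.10:
        raise ConvergenceError(
            f"{100 * div_frac:.1f}% of post-warmup transitions diverged",
            diagnostics=None,
        )

    if check_diagnostics:
        monitored = {}
        for j, gname in enumerate(series.groups):
            for s_idx, sname in enumerate(series.strata):
                for t, tname in enumerate(series.time_labels):
                    monitored[f"eta[{tname},{gname},{sname}]"] = \
                        eta[:, :, t, j, s_idx]
                monitored[f"tau[{gname},{sname}]"] = tau[:, :, j, s_idx]
        report = diagnose(monitored)
        out.diagnostics = report
        if not report.ok:
            warnings.warn(
                f"fit failed convergence gates for {len(report.flags)} "
                f"parameter(s): {report.flags[:5]} (max R-hat "
                f"{report.max_rhat:.4f}, min ESS {report.min_ess:.0f})",
                ConvergenceWarning,
                stacklevel=2,
            )
    return out
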