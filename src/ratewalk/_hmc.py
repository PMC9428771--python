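"""Batched Hamiltonian Monte Carlo with dual-averaging adaptation.

The sampler runs many independent targets at once: positions are arrays of
shape ``(batch, dim)`` where each batch element is one (series, chain)
pair.  All batch elements share the same iteration loop but carry their own
step size and diagonal mass matrix, so chains and independent series mix at
their own pace while the inner arithmetic stays fully vectorized.

Warmup uses the standard windowed scheme: an initial fast phase adapts only
the step size against a unit metric; a sequence of doubling "slow" windows
each re-estimates the diagonal mass matrix from the window's samples and
restarts step-size adaptation; a terminal fast phase re-tunes the step size
against the final metric.  Step sizes are tuned per batch element by
Nesterov dual averaging toward a target acceptance statistic.

An optional Gibbs callback runs after every HMC iteration; the joint
(correlated-series) model uses it to update correlation parameters that are
deliberately kept outside the Hamiltonian flow (see ``frozen_mask``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample"]

# energy error treated as a divergent transition
DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCResult:
    draws: np.ndarray          # (n_keep, batch, dim)
    accept_rate: np.ndarray    # (batch,) post-warmup mean acceptance prob
    divergences: np.ndarray    # (batch,) post-warmup divergent transitions
    n_kept: int
    step_size: np.ndarray      # (batch,) final step sizes


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass, n_steps):
    """Vectorized leapfrog integrator; eps and inv_mass are per-batch."""
    eps = eps[:, None]
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        logp, grad = logp_and_grad(q)
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: np.ndarray, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps_bar = np.log(eps0)
        self.h_bar = np.zeros_like(eps0)
        self.count = 0

    def update(self, accept_prob: np.ndarray) -> np.ndarray:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return np.exp(log_eps)

    @property
    def adapted(self) -> np.ndarray:
        return np.exp(self.log_eps_bar)


def _warmup_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, slow-window end iterations)."""
    if n_warmup < 20:
        return n_warmup, 0, []
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    slow_total = n_warmup - init - term
    ends, size, pos = [], max(slow_total // 15, 25), 0
    while pos + size < slow_total:
        # final window absorbs the remainder rather than leaving a stub
        if pos + 3 * size >= slow_total:
            size = slow_total - pos
        ends.append(init + pos + size)
        pos += size
        size *= 2
    if not ends and slow_total > 0:
        ends.append(init + slow_total)
    return init, term, ends


def _find_initial_step(logp_and_grad, q, eps, inv_mass, rng):
    """Crude per-batch step-size search: double/halve until the one-step
    acceptance probability crosses 1/2 (heuristic of Hoffman & Gelman)."""
    B, D = q.shape
    p = rng.standard_normal((B, D)) / np.sqrt(inv_mass)
    logp, grad = logp_and_grad(q)
    h0 = -logp + 0.5 * np.sum(inv_mass * p * p, axis=1)
    direction = None
    for _ in range(30):
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps,
                                    inv_mass, 1)
        h1 = -logp1 + 0.5 * np.sum(inv_mass * p1 * p1, axis=1)
        delta = np.where(np.isfinite(h1), h0 - h1, -np.inf)
        accept = np.exp(np.minimum(delta, 0.0))
        med = np.median(accept)
        step_dir = 1.0 if med > 0.5 else -1.0
        if direction is None:
            direction = step_dir
        elif step_dir != direction:
            break
        eps = eps * (2.0 ** step_dir)
        if np.any(eps < 1e-10) or np.any(eps > 1e3):
            break
    return np.clip(eps, 1e-8, 10.0)


def sample(
    logp_and_grad: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    q0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 24,
    init_step: float = 0.1,
    gibbs_step: Callable[[np.ndarray, np.random.Generator, bool], np.ndarray]
    | None = None,
    frozen_mask: np.ndarray | None = None,
) -> HMCResult:
    """Draw ``n_draws`` iterations per batch element, retaining the last
    ``n_draws - n_warmup``.

    ``logp_and_grad`` maps positions ``(batch, dim)`` to a tuple of log
    densities ``(batch,)`` and gradients ``(batch, dim)``; non-finite log
    densities lead to rejected transitions.

    Dimensions selected by ``frozen_mask`` receive zero momentum and so
    never move during the Hamiltonian flow; they are updated only by the
    Gibbs callback.  Because they stay constant along each trajectory
    their potential-energy terms cancel in the acceptance ratio, leaving a
    valid conditional update for the remaining dimensions.
    """
    q = np.array(q0, dtype=float)
    B, D = q.shape
    if n_warmup >= n_draws:
        raise ValueError("n_warmup must be < n_draws")

    inv_mass = np.ones((B, D))
    with np.errstate(all="ignore"):
        eps = _find_initial_step(
            logp_and_grad, q, np.full(B, init_step), inv_mass, rng
        )
    da = _DualAveraging(eps, target=target_accept)

    init_buf, term_buf, window_ends = _warmup_schedule(n_warmup)
    window_start = init_buf
    var_sum = np.zeros((B, D))
    var_sumsq = np.zeros((B, D))
    var_n = 0

    n_keep = n_draws - n_warmup
    out = np.empty((n_keep, B, D))
    accept_acc = np.zeros(B)
    div_count = np.zeros(B, dtype=int)

    logp, grad = logp_and_grad(q)
    if not np.all(np.isfinite(logp)):
        raise ValueError("non-finite log density at the initial position")

    with np.errstate(all="ignore"):
        for it in range(n_draws):
            warm = it < n_warmup
            p = rng.standard_normal((B, D)) / np.sqrt(inv_mass)
            if frozen_mask is not None:
                p[:, frozen_mask] = 0.0
            h0 = -logp + 0.5 * np.sum(inv_mass * p * p, axis=1)
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            q_new, p_new, logp_new, grad_new = _leapfrog(
                logp_and_grad, q, p, grad, eps, inv_mass, n_steps
            )
            h1 = -logp_new + 0.5 * np.sum(inv_mass * p_new * p_new, axis=1)
            delta = h0 - h1
            delta = np.where(np.isfinite(delta), delta, -np.inf)
            divergent = delta < -DIVERGENCE_ENERGY
            accept_prob = np.exp(np.minimum(delta, 0.0))
            accept = rng.random(B) < accept_prob
            q = np.where(accept[:, None], q_new, q)
            logp = np.where(accept, logp_new, logp)
            grad = np.where(accept[:, None], grad_new, grad)

            if gibbs_step is not None:
                q = gibbs_step(q, rng, warm)
                logp, grad = logp_and_grad(q)

            if warm:
                eps = da.update(accept_prob)
                if window_ends and it >= window_start:
                    var_sum += q
                    var_sumsq += q * q
                    var_n += 1
                if window_ends and it == window_ends[0] - 1:
                    if var_n > 10:
                        mean = var_sum / var_n
                        var = np.maximum(var_sumsq / var_n - mean * mean, 0.0)
                        shrink = var_n / (var_n + 5.0)
                        var = shrink * var + (1 - shrink) * 1e-3
                        inv_mass = np.maximum(var, 1e-12)
                        eps = da.adapted
                        da = _DualAveraging(eps, target=target_accept)
                    window_start = window_ends.pop(0)
                    var_sum[:] = 0.0
                    var_sumsq[:] = 0.0
                    var_n = 0
                if it == n_warmup - 1:
                    eps = da.adapted
            else:
                out[it - n_warmup] = q
                accept_acc += accept_prob
                div_count += divergent.astype(int)

    return HMCResult(
        draws=out,
        accept_rate=accept_acc / max(n_keep, 1),
        divergences=div_count,
        n_kept=n_keep,
        step_size=eps,
    )
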