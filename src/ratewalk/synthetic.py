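"""Model-consistent synthetic surveillance data.

Runs the generative process of the random-walk model forward: latent
log/logit risks follow a Gaussian (or correlated multivariate-normal)
random walk, and counts are drawn Poisson or binomial given the population
schedule.  The returned :class:`SimulationTruth` records the latent paths
so recovery and calibration tests can compare estimates against the truth
that generated the data.

Each simulated (group, stratum) series consumes its own RNG stream spawned
deterministically from the master seed, so adding a series never perturbs
the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io import CaseSeries

__all__ = ["SimulationTruth", "simulate"]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulation run."""

    eta: np.ndarray            # (time, group, stratum)
    tau: np.ndarray            # (group, stratum)
    corr: np.ndarray | None    # (k, k) increment correlation, if any
    populations: np.ndarray    # (time, group, stratum)
    seed: int

    def rates(self, family: str = "poisson", per: float = 1.0) -> np.ndarray:
        link = np.exp if family == "poisson" else expit
        return per * link(self.eta)


def _as_labels(x, prefix: str) -> tuple:
    if isinstance(x, int):
        if x < 1:
            raise ValueError(f"need at least one {prefix}")
        return tuple(f"{prefix}{i + 1}" for i in range(x)) if x > 1 else ("all",)
    return tuple(x)


def simulate(
    n_periods: int,
    groups=1,
    strata=1,
    eta1: float | np.ndarray = -5.0,
    tau: float | np.ndarray = 0.05,
    populations: float | np.ndarray = 1e6,
    family: str = "poisson",
    corr: np.ndarray | None = None,
    population_growth: float = 0.0,
    first_period: int = 1999,
    seed: int = 0,
) -> tuple[CaseSeries, SimulationTruth]:
    """Simulate a surveillance panel from the random-walk model.

    Parameters
    ----------
    n_periods
        Number of evenly spaced periods (labeled as calendar years from
        ``first_period``).
    groups, strata
        Either counts or explicit label sequences.
    eta1
        Initial log (Poisson) or logit (binomial) risk, broadcastable to
        ``(group, stratum)``.
    tau
        Increment scale per series, broadcastable to ``(group, stratum)``;
        ``tau=0`` gives a constant-risk series.
    populations
        Population at risk, broadcastable to ``(time, group, stratum)``;
        a deterministic geometric growth ``population_growth`` per period
        may be applied on top of a time-constant base.
    corr
        Optional k x k correlation matrix for the group increments (shared
        across strata); ``None`` simulates independent walks.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if family not in ("poisson", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    group_labels = _as_labels(groups, "group")
    strata_labels = _as_labels(strata, "stratum")
    k, m = len(group_labels), len(strata_labels)
    n = n_periods

    def _per_series(x, name):
        # a length-k vector means "per group"; anything else must
        # broadcast to (group, stratum)
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1 and arr.shape[0] == k and (k != m or m == 1):
            arr = arr[:, None]
        try:
            return np.broadcast_to(arr, (k, m)).copy()
        except ValueError:
            raise ValueError(
                f"{name} with shape {arr.shape} does not broadcast to "
                f"(groups, strata) = ({k}, {m})"
            ) from None

    tau_arr = _per_series(tau, "tau")
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    eta1_arr = _per_series(eta1, "eta1")

    pops = np.asarray(populations, dtype=float)
    if pops.ndim == 1 and pops.shape[0] == k and (k != m or m == 1):
        pops = pops[:, None]
    if pops.ndim <= 2:
        pops = np.broadcast_to(pops, (k, m))[None, :, :]
    pops = np.broadcast_to(pops, (n, k, m)).copy()
    if population_growth != 0.0:
        growth = (1.0 + population_growth) ** np.arange(n)
        pops = pops * growth[:, None, None]
    if np.any(pops <= 0):
        raise ValueError("populations must be > 0")

    chol = None
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"corr must be ({k}, {k}); got {corr.shape}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1):
            raise ValueError("corr must be a symmetric correlation matrix")
        chol = np.linalg.cholesky(corr)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(k * m + 1)
    count_rng = np.random.default_rng(streams[-1])

    eta = np.empty((n, k, m))
    if chol is None:
        for j in range(k):
            for s in range(m):
                rng = np.random.default_rng(streams[j * m + s])
                steps = tau_arr[j, s] * rng.standard_normal(n - 1) \
                    if n > 1 else np.empty(0)
                eta[:, j, s] = eta1_arr[j, s] + np.concatenate(
                    [[0.0], np.cumsum(steps)]
                )
    else:
        # correlated increments across groups, one stream per stratum
        for s in range(m):
            rng = np.random.default_rng(streams[s])
            zs = rng.standard_normal((n - 1, k)) if n > 1 else np.empty((0, k))
            inc = zs @ chol.T * tau_arr[:, s]
            eta[:, :, s] = eta1_arr[:, s] + np.concatenate(
                [np.zeros((1, k)), np.cumsum(inc, axis=0)], axis=0
            )

    if family == "poisson":
        mu = pops * np.exp(eta)
        counts = count_rng.poisson(mu)
    else:
        if np.any(pops != np.floor(pops)):
            raise ValueError("binomial family requires integral populations")
        counts = count_rng.binomial(pops.astype(np.int64), expit(eta))

    labels = tuple(str(first_period + t) for t in range(n))
    series = CaseSeries(
        time_labels=labels,
        groups=group_labels,
        strata=strata_labels,
        counts=counts,
        populations=pops,
    )
    truth = SimulationTruth(
        eta=eta, tau=tau_arr, corr=corr, populations=pops, seed=seed
    )
    return series, truth
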