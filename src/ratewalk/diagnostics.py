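"""MCMC convergence diagnostics and posterior summarization.

Convergence is assessed with the classic split potential-scale-reduction
statistic (split R-hat): each chain is cut in half and the usual
between/within variance ratio is computed over the resulting half-chains.
Precision is assessed through the Monte Carlo standard error of the
posterior mean, sd/sqrt(ESS), with bulk effective sample size taken from
``arviz``.

Gates (conventions of this package; they can be tightened by callers):

* split R-hat < 1.01 for every monitored parameter,
* MCSE of the mean < 10% of the posterior standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "RateSummary",
    "DiagnosticsReport",
    "ConvergenceWarning",
    "split_rhat",
    "ess_bulk",
    "mcse_mean",
    "summarize",
    "diagnose",
]

RHAT_GATE = 1.01
MCSE_SD_FRACTION_GATE = 0.10


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when a fit fails the diagnostic gates."""


@dataclass(frozen=True)
class RateSummary:
    """Posterior mean and equal-tailed credible interval for one quantity."""

    mean: float
    lwr: float
    upr: float
    quantity: str = ""
    time: object = None
    group: object = None
    stratum: object = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.quantity or 'quantity'}: {self.mean:.6g} "
            f"({self.lwr:.6g} to {self.upr:.6g})"
        )


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics for one fit."""

    names: list
    split_rhat: np.ndarray
    ess_bulk: np.ndarray
    mcse_mean: np.ndarray
    sd: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    @property
    def max_rhat(self) -> float:
        return float(np.max(self.split_rhat))

    @property
    def min_ess(self) -> float:
        return float(np.min(self.ess_bulk))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.names,
                "split_rhat": self.split_rhat,
                "ess_bulk": self.ess_bulk,
                "mcse_mean": self.mcse_mean,
                "sd": self.sd,
                "flagged": [n in set(self.flags) for n in self.names],
            }
        )


def _check_draws(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError(
            f"draws must be (chains, draws) for a scalar parameter; got "
            f"shape {draws.shape}"
        )
    c, n = draws.shape
    if c < 2:
        raise ValueError("need at least 2 chains")
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    return draws


def split_rhat(draws: np.ndarray) -> float:
    """Classic split potential-scale-reduction statistic.

    Each of the C chains is split in half, giving 2C half-chains of length
    L.  With W the mean within-half-chain variance and B the between-means
    variance statistic, R-hat = sqrt(((L-1)/L * W + B/L) / W).  Values near
    1 indicate the chains have mixed; the gate used here is 1.01.
    """
    draws = _check_draws(draws)
    c, n = draws.shape
    half = n // 2
    halves = np.concatenate(
        [draws[:, :half], draws[:, n - half:]], axis=0
    )  # (2c, half)
    if np.ptp(halves) == 0:
        raise ValueError("degenerate draws: zero total variance")
    L = half
    within = halves.var(axis=1, ddof=1)  # per half-chain
    w = within.mean()
    if w == 0:
        raise ValueError("degenerate draws: zero within-chain variance")
    means = halves.mean(axis=1)
    b = L * means.var(ddof=1)
    var_plus = (L - 1) / L * w + b / L
    return float(np.sqrt(var_plus / w))


def ess_bulk(draws: np.ndarray) -> float:
    """Bulk effective sample size (rank-normalized, via arviz)."""
    draws = _check_draws(draws)
    if np.ptp(draws) == 0:
        raise ValueError("degenerate draws: zero total variance")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = az.ess(np.asarray(draws), method="bulk")
    return float(val)


def mcse_mean(draws: np.ndarray) -> float:
    """Monte Carlo standard error of the posterior mean, sd/sqrt(ESS)."""
    draws = _check_draws(draws)
    ess = ess_bulk(draws)
    return float(draws.std(ddof=1) / np.sqrt(ess))


def summarize(
    draws: np.ndarray,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    level: float = 0.95,
    **labels,
) -> RateSummary:
    """Posterior mean and equal-tailed interval of (a transform of) draws.

    The transform is applied per draw *before* averaging, so the summary is
    of the transformed quantity; the mean of a nonlinear transform is not
    the transform of the mean.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("summarize: empty draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("summarize: non-finite draws")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1); got {level}")
    x = draws if transform is None else np.asarray(transform(draws), dtype=float)
    alpha = (1.0 - level) / 2.0
    lwr, upr = np.quantile(x, [alpha, 1.0 - alpha])
    return RateSummary(mean=float(x.mean()), lwr=float(lwr), upr=float(upr),
                       **labels)


def diagnose(
    draws_by_name: dict,
    rhat_gate: float = RHAT_GATE,
    mcse_fraction_gate: float = MCSE_SD_FRACTION_GATE,
) -> DiagnosticsReport:
    """Run the diagnostic gates over a dict of named (chains, draws) arrays.

    Parameters whose draws are (numerically) constant are reported with
    R-hat 1 and are never flagged: a degenerate posterior is converged by
    definition (it arises e.g. for tau when the prior pins it).
    """
    names, rhats, esss, mcses, sds, flags = [], [], [], [], [], []
    for name, d in draws_by_name.items():
        d = np.asarray(d, dtype=float)
        names.append(name)
        sd = d.std(ddof=1)
        sds.append(sd)
        spread = np.ptp(d)
        scale = max(abs(d).max(), 1.0)
        if spread <= 1e-12 * scale:
            rhats.append(1.0)
            esss.append(float(d.shape[0] * d.shape[1]))
            mcses.append(0.0)
            continue
        r = split_rhat(d)
        e = ess_bulk(d)
        m = float(sd / np.sqrt(e))
        rhats.append(r)
        esss.append(e)
        mcses.append(m)
        if r >= rhat_gate or (sd > 0 and m >= mcse_fraction_gate * sd):
            flags.append(name)
    return DiagnosticsReport(
        names=names,
        split_rhat=np.array(rhats),
        ess_bulk=np.array(esss),
        mcse_mean=np.array(mcses),
        sd=np.array(sds),
        flags=flags,
    )
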