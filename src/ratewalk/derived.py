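"""Percent-change metrics on the rate scale.

All change metrics are computed per posterior draw and only then
summarized: the posterior mean of a ratio is not the ratio of posterior
means, so computing changes from already-summarized rates would misstate
both the point estimate and the interval.

Definitions, with R_t the rate at period t:

* annual percent change      APC_t = 100 (R_t / R_{t-1} - 1),  t = 2..n
* cumulative percent change  CPC_t = 100 (R_t / R_1 - 1)
* average annual percent change over a window = arithmetic mean of the
  APC_t whose transitions lie inside the window (a geometric-mean variant
  is available).

The kernels accept any array with time on the last axis, so they apply
equally to point rates (e.g. published table values) and to posterior draw
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnostics import RateSummary, summarize
from .model import PosteriorDraws
from .standardize import StandardPopulation, direct_standardize

__all__ = [
    "ChangeSeries",
    "apc",
    "cpc",
    "aapc_points",
    "round_half_away",
    "apc_series",
    "cumulative_percent_change",
    "aapc",
]


# ---------------------------------------------------------------------------
# array kernels (time on the last axis)

def apc(rates: np.ndarray) -> np.ndarray:
    """Annual percent change per transition; output has n-1 time entries."""
    r = np.asarray(rates, dtype=float)
    if r.shape[-1] < 2:
        raise ValueError("need at least 2 periods for percent change")
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    return 100.0 * (r[..., 1:] / r[..., :-1] - 1.0)


def cpc(rates: np.ndarray) -> np.ndarray:
    """Cumulative percent change relative to the first period (0 at t=1)."""
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    return 100.0 * (r / r[..., :1] - 1.0)


def aapc_points(rates: np.ndarray, geometric: bool = False) -> np.ndarray:
    """Average annual percent change over all transitions of ``rates``."""
    a = apc(rates)
    if geometric:
        return 100.0 * (np.exp(np.mean(np.log1p(a / 100.0), axis=-1)) - 1.0)
    return np.mean(a, axis=-1)


def round_half_away(x):
    """Round half away from zero (the convention of published rate tables;
    numpy's ``round`` rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# posterior wrappers

@dataclass
class ChangeSeries:
    """Per-draw change metrics with their posterior summaries."""

    time_labels: tuple
    apc_draws: np.ndarray   # (chain, draw, n-1)
    cpc_draws: np.ndarray   # (chain, draw, n)
    apc_summary: list
    cpc_summary: list


def _select_rates(draws: PosteriorDraws, group, stratum,
                  std: StandardPopulation | None, per: float) -> np.ndarray:
    if std is not None:
        return direct_standardize(draws, std, group=group, per=per)
    return draws.rate_draws(group=group, stratum=stratum, per=per)


def apc_series(
    draws: PosteriorDraws,
    group=None,
    stratum=None,
    std: StandardPopulation | None = None,
    level: float = 0.95,
) -> ChangeSeries:
    """Annual and cumulative percent change for one (possibly
    age-standardized) series, summarized per period."""
    rates = _select_rates(draws, group, stratum, std, per=1.0)
    labels = draws.series.time_labels
    a = apc(rates)
    c = cpc(rates)
    a_sum = [
        summarize(a[..., t], level=level, quantity="apc",
                  time=labels[t + 1], group=group, stratum=stratum)
        for t in range(a.shape[-1])
    ]
    c_sum = [
        summarize(c[..., t], level=level, quantity="cpc",
                  time=labels[t], group=group, stratum=stratum)
        for t in range(c.shape[-1])
    ]
    return ChangeSeries(
        time_labels=labels, apc_draws=a, cpc_draws=c,
        apc_summary=a_sum, cpc_summary=c_sum,
    )


def cumulative_percent_change(
    draws: PosteriorDraws,
    group=None,
    stratum=None,
    std: StandardPopulation | None = None,
    level: float = 0.95,
) -> list:
    """Posterior summaries of 100 (R_t / R_1 - 1) per period."""
    return apc_series(draws, group=group, stratum=stratum, std=std,
                      level=level).cpc_summary


def aapc(
    draws: PosteriorDraws,
    window,
    group=None,
    stratum=None,
    std: StandardPopulation | None = None,
    geometric: bool = False,
    level: float = 0.95,
) -> RateSummary:
    """Average annual percent change over a contiguous window of periods.

    ``window`` is a sequence of consecutive time labels (or integer
    indices); the AAPC averages the APCs of the transitions *within* the
    window, per draw, so the credible interval is a true posterior
    interval for the average change.
    """
    labels = list(draws.series.time_labels)
    idx = []
    for wlab in window:
        if isinstance(wlab, (int, np.integer)) and wlab not in labels \
                and str(wlab) not in labels:
            idx.append(int(wlab))
        else:
            key = wlab if wlab in labels else str(wlab)
            if key not in labels:
                raise ValueError(f"period {wlab!r} not in series")
            idx.append(labels.index(key))
    idx = sorted(idx)
    if len(idx) < 2:
        raise ValueError("window must span at least 2 periods")
    if idx[0] < 0 or idx[-1] >= len(labels):
        raise ValueError("window out of range")
    if np.any(np.diff(idx) != 1):
        raise ValueError(f"window periods must be contiguous; got {window}")
    rates = _select_rates(draws, group, stratum, std, per=1.0)
    window_rates = rates[..., idx[0]: idx[-1] + 1]
    a = apc(window_rates)
    if geometric:
        per_draw = 100.0 * (
            np.exp(np.mean(np.log1p(a / 100.0), axis=-1)) - 1.0
        )
    else:
        per_draw = np.mean(a, axis=-1)
    return summarize(
        per_draw, level=level, quantity="aapc",
        time=f"{labels[idx[0]]}-{labels[idx[-1]]}", group=group,
        stratum=stratum,
    )
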