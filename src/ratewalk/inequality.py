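"""Health-inequality measures computed per posterior draw.

Pairwise measures compare a disadvantaged group (subscript d) with an
advantaged group (subscript a); which is which is declared by the caller,
never inferred from the data, because rate rankings can flip between
draws and a silently flipping reference would corrupt the intervals.

Crude pairwise measures, per period:

* rate ratio                 RR  = R_d / R_a
* rate difference            RD  = R_d - R_a
* proportion attributable risk  PAR = RD / R_d  (= 1 - 1/RR)
* excess cases               EC  = RD * P_d
* cumulative EC              sum_t EC_t
* cumulative PAR             sum_t EC_t / sum_t (R_dt P_dt)

Age-standardized comparisons use standardized rates for RR/RD, but excess
cases must be accumulated stratum by stratum, EC = sum_i (R_di - R_ai)
P_di, and only then divided by total expected burden for the PAR —
standardized rates weight strata by the standard population rather than
the actual one, so computing EC from them would miscount cases.

The Theil index compares each group's share of expected disease burden
with its share of the population, T = sum_j w_j ln(w_j / p_j) with
w_j = R_j P_j / sum R P and p_j = P_j / sum P.  It is nonnegative, zero
exactly when burden shares match population shares, and decomposes
additively over nested units (e.g. groups within regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnostics import summarize
from .model import PosteriorDraws
from .standardize import StandardPopulation, direct_standardize

__all__ = [
    "PairwiseInequality",
    "StandardizedPairwiseInequality",
    "TheilResult",
    "pairwise",
    "standardized_pairwise",
    "par_to_rr",
    "theil",
    "theil_decomposition",
]


# ---------------------------------------------------------------------------
# results

@dataclass
class PairwiseInequality:
    """Per-draw crude pairwise measures; arrays are (chain, draw, time)
    except the cumulative measures, which are (chain, draw)."""

    group_d: object
    group_a: object
    time_labels: tuple
    rr: np.ndarray
    rd: np.ndarray
    par: np.ndarray
    ec: np.ndarray
    cumulative_ec: np.ndarray
    cumulative_par: np.ndarray

    def summary(self, level: float = 0.95):
        import pandas as pd

        rows = []
        for name, arr in (("rr", self.rr), ("rd", self.rd),
                          ("par", self.par), ("ec", self.ec)):
            for t, lab in enumerate(self.time_labels):
                s = summarize(arr[..., t], level=level)
                rows.append((lab, name, s.mean, s.lwr, s.upr))
        for name, arr in (("cumulative_ec", self.cumulative_ec),
                          ("cumulative_par", self.cumulative_par)):
            s = summarize(arr, level=level)
            rows.append(("total", name, s.mean, s.lwr, s.upr))
        return pd.DataFrame(
            rows, columns=["time", "measure", "mean", "lwr_2.5", "upr_97.5"]
        )


@dataclass
class StandardizedPairwiseInequality(PairwiseInequality):
    """Age-standardized pairwise measures (RR/RD from standardized rates;
    EC and PAR from stratum-level sums)."""


@dataclass
class TheilResult:
    """Theil index draws; ``total`` is (chain, draw, time), ``components``
    adds a trailing group axis."""

    time_labels: tuple
    groups: tuple
    total: np.ndarray
    components: np.ndarray
    between: np.ndarray | None = None
    within: np.ndarray | None = None

    def summary(self, level: float = 0.95):
        import pandas as pd

        rows = []
        for t, lab in enumerate(self.time_labels):
            s = summarize(self.total[..., t], level=level)
            rows.append((lab, "theil", s.mean, s.lwr, s.upr))
            if self.between is not None:
                sb = summarize(self.between[..., t], level=level)
                rows.append((lab, "theil_between", sb.mean, sb.lwr, sb.upr))
        return pd.DataFrame(
            rows, columns=["time", "measure", "mean", "lwr_2.5", "upr_97.5"]
        )


# ---------------------------------------------------------------------------
# pairwise measures

def _group_populations(series, group) -> np.ndarray:
    """Population of one group summed over strata, (time,)."""
    j = series.group_index(group)
    return series.populations[:, j, :].sum(axis=1)


def pairwise(draws: PosteriorDraws, group_d, group_a) -> PairwiseInequality:
    """Crude pairwise inequality between two groups of a fitted panel.

    Rates are the model's per-draw risks (per person); populations at risk
    for the disadvantaged group come from the fitted series.
    """
    if group_d == group_a:
        raise ValueError("group_d and group_a must differ")
    rd_rates = draws.rate_draws(group=group_d)
    ra_rates = draws.rate_draws(group=group_a)
    p_d = _group_populations(draws.series, group_d)
    rr = rd_rates / ra_rates
    rd = rd_rates - ra_rates
    par = rd / rd_rates
    ec = rd * p_d
    burden_d = rd_rates * p_d
    cum_ec = ec.sum(axis=-1)
    cum_par = cum_ec / burden_d.sum(axis=-1)
    return PairwiseInequality(
        group_d=group_d, group_a=group_a,
        time_labels=draws.series.time_labels,
        rr=rr, rd=rd, par=par, ec=ec,
        cumulative_ec=cum_ec, cumulative_par=cum_par,
    )


def standardized_pairwise(
    draws: PosteriorDraws,
    std: StandardPopulation,
    group_d,
    group_a,
) -> StandardizedPairwiseInequality:
    """Age-standardized pairwise inequality.

    RR and RD are ratios/differences of directly standardized rates.
    Excess cases are computed separately within each age stratum against
    the disadvantaged group's actual stratum populations and then summed;
    the PAR divides these by the total expected burden
    sum_i R_di P_di.
    """
    if group_d == group_a:
        raise ValueError("group_d and group_a must differ")
    sr_d = direct_standardize(draws, std, group=group_d)
    sr_a = direct_standardize(draws, std, group=group_a)
    srr = sr_d / sr_a
    srd = sr_d - sr_a

    r_d = draws.stratum_rate_draws(group=group_d)  # (c, t, n, strata)
    r_a = draws.stratum_rate_draws(group=group_a)
    jd = draws.series.group_index(group_d)
    p_d = draws.series.populations[:, jd, :]  # (n, strata)
    ec = ((r_d - r_a) * p_d).sum(axis=-1)     # (c, t, n)
    burden = (r_d * p_d).sum(axis=-1)
    par = ec / burden
    cum_ec = ec.sum(axis=-1)
    cum_par = cum_ec / burden.sum(axis=-1)
    return StandardizedPairwiseInequality(
        group_d=group_d, group_a=group_a,
        time_labels=draws.series.time_labels,
        rr=srr, rd=srd, par=par, ec=ec,
        cumulative_ec=cum_ec, cumulative_par=cum_par,
    )


def par_to_rr(par):
    """Rate ratio equivalent to a proportion attributable risk.

    RR = (1/PAR) / (1/PAR - 1); the inverse of PAR = 1 - 1/RR.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par <= 0) or np.any(par >= 1):
        raise ValueError("par must lie strictly within (0, 1)")
    inv = 1.0 / par
    out = inv / (inv - 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Theil index

def _theil_kernel(rates, pops):
    """Theil index over the last (group) axis.

    ``rates``: (..., k); ``pops``: broadcastable (..., k).  Returns
    (total (...,), components (..., k))."""
    burden = rates * pops
    tot_b = burden.sum(axis=-1, keepdims=True)
    if np.any(burden <= 0):
        raise ValueError("Theil index requires positive burden shares")
    w = burden / tot_b
    p = pops / np.sum(pops, axis=-1, keepdims=True)
    comp = w * np.log(w / p)
    return comp.sum(axis=-1), comp


def theil(draws: PosteriorDraws, stratum=None) -> TheilResult:
    """Theil index across the groups of a fitted panel, per draw and
    period."""
    series = draws.series
    if series.n_groups < 2:
        raise ValueError("Theil index requires at least 2 groups")
    if stratum is None and series.n_strata > 1:
        raise ValueError("specify a stratum for multi-stratum panels")
    s_idx = 0 if stratum is None else series.stratum_index(stratum)
    rates = np.stack(
        [
            draws.rate_draws(group=g, stratum=series.strata[s_idx])
            for g in series.groups
        ],
        axis=-1,
    )  # (chain, draw, time, k)
    pops = series.populations[:, :, s_idx]  # (time, k)
    total, comp = _theil_kernel(rates, pops)
    return TheilResult(
        time_labels=series.time_labels, groups=series.groups,
        total=total, components=comp,
    )


def theil_decomposition(
    draws: PosteriorDraws,
    nesting: dict,
    stratum=None,
) -> TheilResult:
    """Between/within decomposition of the Theil index over nested units.

    ``nesting`` maps each group label to a unit label.  Per draw and
    period: T_between is the Theil index over unit aggregates (burden and
    population summed within unit) and T_total = T_between +
    sum_u s_u T_within_u with s_u the unit's burden share; the identity
    holds exactly, draw by draw.
    """
    series = draws.series
    missing = set(series.groups) - set(nesting)
    if missing:
        raise ValueError(f"nesting lacks groups {sorted(map(str, missing))}")
    units = list(dict.fromkeys(nesting[g] for g in series.groups))
    if len(units) < 1:
        raise ValueError("need at least one unit")
    base = theil(draws, stratum=stratum)
    s_idx = 0 if stratum is None else series.stratum_index(stratum)
    rates = np.stack(
        [
            draws.rate_draws(group=g, stratum=series.strata[s_idx])
            for g in series.groups
        ],
        axis=-1,
    )
    pops = series.populations[:, :, s_idx]
    burden = rates * pops
    tot_b = burden.sum(axis=-1, keepdims=True)
    tot_p = pops.sum(axis=-1, keepdims=True)

    unit_of = np.array([units.index(nesting[g]) for g in series.groups])
    nunits = len(units)
    unit_b = np.stack(
        [burden[..., unit_of == u].sum(axis=-1) for u in range(nunits)],
        axis=-1,
    )
    unit_p = np.stack(
        [pops[..., unit_of == u].sum(axis=-1) for u in range(nunits)],
        axis=-1,
    )
    wu = unit_b / tot_b
    pu = unit_p / tot_p
    between = (wu * np.log(wu / pu)).sum(axis=-1)

    within = np.zeros_like(between)
    for u in range(nunits):
        mask = unit_of == u
        if mask.sum() < 1:
            continue
        w_in = burden[..., mask] / unit_b[..., u: u + 1]
        p_in = pops[..., mask] / unit_p[..., u: u + 1]
        t_in = (w_in * np.log(w_in / p_in)).sum(axis=-1)
        within = within + wu[..., u] * t_in
    return TheilResult(
        time_labels=series.time_labels, groups=series.groups,
        total=base.total, components=base.components,
        between=between, within=within,
    )
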