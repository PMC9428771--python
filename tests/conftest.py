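"""Shared fixtures: small fitted posteriors reused across test modules."""

import numpy as np
import pytest

import ratewalk as rw
from ratewalk.diagnostics import RateSummary
from ratewalk.model import PosteriorDraws


@pytest.fixture(scope="session")
def panel_posterior():
    """A fitted 2-group x 2-stratum panel with moderate counts.

    Fit once per session; used by the derived/standardize/inequality
    tests, which only need valid posterior draws, not a converged
    full-protocol run.
    """
    series, truth = rw.simulate(
        n_periods=10,
        groups=("black", "white"),
        strata=("50-64", "65-79"),
        eta1=np.log(np.array([[150.0, 220.0], [110.0, 170.0]]) / 1e5),
        tau=0.04,
        populations=np.array([[4e5, 2e5], [9e5, 5e5]]),
        seed=314,
    )
    spec = rw.ModelSpec(chains=2, draws_per_chain=900, warmup=450, seed=27)
    post = rw.fit(series, spec, check_diagnostics=False)
    return series, truth, post


@pytest.fixture(scope="session")
def single_series_posterior():
    """A fitted single-series posterior with near-constant risk."""
    series, truth = rw.simulate(
        n_periods=12, eta1=np.log(1e-3), tau=0.03, populations=1e6, seed=99
    )
    spec = rw.ModelSpec(chains=2, draws_per_chain=900, warmup=450, seed=7)
    post = rw.fit(series, spec, check_diagnostics=False)
    return series, truth, post


def make_point_posterior(rates_by_group, populations, strata=("all",),
                         time_labels=None, family="poisson"):
    """Build a degenerate PosteriorDraws whose draws all equal fixed rates.

    ``rates_by_group``: dict group -> array (time,) or (time, stratum) of
    rates per person.  Used to check derived-quantity arithmetic against
    hand calculations without running MCMC.
    """
    groups = tuple(rates_by_group)
    arrs = [np.atleast_2d(np.asarray(r, float).T).T for r in
            rates_by_group.values()]
    n = arrs[0].shape[0]
    m = len(strata)
    rates = np.stack([a.reshape(n, m) for a in arrs], axis=1)  # (n, k, m)
    if time_labels is None:
        time_labels = tuple(str(1999 + t) for t in range(n))
    pops = np.broadcast_to(np.asarray(populations, float), (n, len(groups), m))
    counts = np.rint(rates * pops).astype(int)
    series = rw.CaseSeries(
        time_labels=time_labels, groups=groups, strata=strata,
        counts=counts, populations=pops.copy(),
    )
    eta = np.log(rates) if family == "poisson" else \
        np.log(rates / (1 - rates))
    # two chains x four draws, all identical
    eta_draws = np.broadcast_to(eta, (2, 4) + eta.shape).copy()
    tau_draws = np.full((2, 4, len(groups), m), 0.01)
    spec = rw.ModelSpec(family=family, chains=2, draws_per_chain=8, warmup=4)
    return PosteriorDraws(eta=eta_draws, tau=tau_draws, corr=None,
                          spec=spec, series=series)


@pytest.fixture
def point_posterior_factory():
    return make_point_posterior


@pytest.fixture
def summaries_small():
    return [
        RateSummary(mean=129.0, lwr=123.0, upr=136.0,
                    quantity="rate_per_100k", time="2018", group="black",
                    stratum="all"),
        RateSummary(mean=94.37, lwr=91.2, upr=97.9,
                    quantity="rate_per_100k", time="2018", group="white",
                    stratum="all"),
        RateSummary(mean=-31.4, lwr=-37.0, upr=-25.0, quantity="cpc",
                    time="2018", group="black", stratum="all"),
    ]
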