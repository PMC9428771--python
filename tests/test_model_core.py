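"""Model densities, gradients, and posterior correctness of the sampler."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import ratewalk as rw
from ratewalk import model as M
from ratewalk.model import ModelSpec, fit, log_likelihood, log_prior_density


class TestLogPriorDensity:
    def test_single_period_closed_form(self):
        """n=1 at the prior mode: Gaussian log-pdf plus half-normal term."""
        spec = ModelSpec()
        tau = 0.3
        got = log_prior_density([-5.0], tau, spec)
        want = stats.norm.logpdf(-5.0, -5.0, 5.0) \
            + stats.halfnorm.logpdf(tau, scale=1.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_constant_path_increment_terms(self):
        """A flat path contributes log N(0|0, tau^2) per transition."""
        spec = ModelSpec()
        tau = 0.123
        base = log_prior_density([-4.2], tau, spec)
        got = log_prior_density([-4.2, -4.2, -4.2], tau, spec)
        assert got - base == pytest.approx(
            2 * stats.norm.logpdf(0.0, 0.0, tau), rel=1e-12
        )

    def test_tau_prior_term_is_separable(self):
        """Doubling the half-normal scale changes only the tau term."""
        eta = [-5.0, -4.9, -5.1]
        tau = 0.2
        a = log_prior_density(eta, tau, ModelSpec(tau_prior_sd=1.0))
        b = log_prior_density(eta, tau, ModelSpec(tau_prior_sd=2.0))
        want = stats.halfnorm.logpdf(tau, scale=2.0) \
            - stats.halfnorm.logpdf(tau, scale=1.0)
        assert b - a == pytest.approx(want, rel=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            log_prior_density([-5.0], 0.0, ModelSpec())


class TestLogLikelihood:
    def test_poisson_zero_count(self):
        """P(y=0) = exp(-mu), so the log-pmf is -1000 e^-5."""
        got = log_likelihood([0], [1000.0], [-5.0], family="poisson")
        assert got == pytest.approx(-1000.0 * np.exp(-5.0), rel=1e-12)

    def test_binomial_logit_zero_is_half(self):
        got = log_likelihood([3], [10], [0.0], family="binomial")
        assert got == pytest.approx(stats.binom.logpmf(3, 10, 0.5), rel=1e-12)

    def test_poisson_mode_at_rounded_mean(self):
        """The per-period term is maximized over integers near mu."""
        p, eta = 900.0, -4.1
        mu = p * np.exp(eta)
        lls = [log_likelihood([y], [p], [eta]) for y in range(50)]
        assert int(np.argmax(lls)) in (int(np.floor(mu)), int(np.ceil(mu)))

    def test_binomial_count_exceeding_population(self):
        with pytest.raises(ValueError, match="y_t <= P_t"):
            log_likelihood([11], [10], [0.0], family="binomial")


@pytest.mark.parametrize("family", ["poisson", "binomial"])
def test_sampler_target_gradient_matches_finite_differences(family):
    """The fused log-density gradient agrees with central differences."""
    rng = np.random.default_rng(5)
    n = 6
    p = np.full((3, n), 5000.0)
    y = rng.poisson(5000 * np.exp(-5), size=(3, n)).astype(float)
    spec = ModelSpec(family=family)
    target = M._make_target_independent(y, p, spec)
    q = rng.normal(0, 0.5, size=(3, n + 1))
    logp, grad = target(q)
    eps = 1e-6
    for d in range(n + 1):
        qp, qm = q.copy(), q.copy()
        qp[:, d] += eps
        qm[:, d] -= eps
        num = (target(qp)[0] - target(qm)[0]) / (2 * eps)
        np.testing.assert_allclose(grad[:, d], num, rtol=2e-5, atol=1e-5)


def test_sampler_target_differences_match_reference_densities():
    """Log-density differences of the fused target equal differences of
    the reference prior x likelihood (constants cancel), including the
    log-tau Jacobian."""
    rng = np.random.default_rng(2)
    n = 5
    y = rng.poisson(40, size=(1, n)).astype(float)
    p = np.full((1, n), 40000.0)
    spec = ModelSpec()
    target = M._make_target_independent(y, p, spec)

    def reference(q):
        z, lt = q[:n], q[n]
        tau = np.exp(lt)
        steps = np.r_[spec.eta1_prior_sd, np.full(n - 1, tau)]
        eta = spec.eta1_prior_mean + np.cumsum(steps * z)
        return (
            log_prior_density(eta, tau, spec)
            + log_likelihood(y[0], p[0], eta)
            # change of variables: (eta_2..n, tau) -> (z_2..n, log tau)
            + (n - 1) * np.log(tau) + np.log(spec.eta1_prior_sd) + lt
        )

    q1 = rng.normal(0, 0.4, size=n + 1)
    q2 = rng.normal(0, 0.4, size=n + 1)
    got = target(q1[None])[0][0] - target(q2[None])[0][0]
    want = reference(q1) - reference(q2)
    assert got == pytest.approx(want, rel=1e-9)


def test_joint_target_gradient_matches_finite_differences():
    rng = np.random.default_rng(11)
    n, k = 4, 3
    y = rng.poisson(50, size=(2, n, k)).astype(float)
    p = np.full((2, n, k), 50000.0)
    spec = ModelSpec(joint=True)
    target, _ = M._make_target_joint(y, p, spec, k)
    dim = n * k + k + k * (k - 1) // 2
    q = rng.normal(0, 0.3, size=(2, dim))
    logp, grad = target(q)
    eps = 1e-6
    for d in range(n * k + k):  # u dims carry zero gradient by design
        qp, qm = q.copy(), q.copy()
        qp[:, d] += eps
        qm[:, d] -= eps
        num = (target(qp)[0] - target(qm)[0]) / (2 * eps)
        np.testing.assert_allclose(grad[:, d], num, rtol=2e-5, atol=1e-5)


class TestFit:
    def test_constant_risk_recovery(self):
        """Posterior rate stays within 3 posterior SDs of the generator
        truth (100/100k) at every period; per-period MLE y/P is the
        sanity anchor."""
        series, truth = rw.simulate(
            n_periods=20, populations=1e6, eta1=np.log(100 / 1e5), tau=0.0,
            seed=42,
        )
        post = fit(series, ModelSpec(chains=4, draws_per_chain=1500,
                                     warmup=750, seed=1))
        rates = post.rate_draws(per=1e5)
        mean = rates.mean(axis=(0, 1))
        sd = rates.std(axis=(0, 1))
        assert np.all(np.abs(mean - 100.0) < 3 * sd)
        # sanity anchor: per-period MLE y/P, allowing its own sampling
        # noise sqrt(y)/P (the model smooths across periods)
        mle = 1e5 * series.counts[:, 0, 0] / series.populations[:, 0, 0]
        mle_se = 1e5 * np.sqrt(series.counts[:, 0, 0]) \
            / series.populations[:, 0, 0]
        assert np.all(np.abs(mean - mle) < 4 * mle_se)

    def test_single_period_large_count(self):
        """n=1 with y=10000, P=1e7: the posterior rate concentrates at
        y/P (Poisson-gamma large-count limit), within 2%."""
        series = rw.CaseSeries(
            ("1999",), ("all",), ("all",),
            np.array([[[10000]]]), np.array([[[1e7]]]),
        )
        post = fit(series, ModelSpec(chains=2, draws_per_chain=1200,
                                     warmup=600, seed=4),
                   check_diagnostics=False)
        mean_rate = post.rate_draws(per=1e5).mean()
        assert mean_rate == pytest.approx(100.0, rel=0.02)

    def test_joint_independent_series_modest_correlation(self):
        """k=2 simulated independently: posterior mean off-diagonal
        correlation stays in [-0.5, 0.5] (truth 0, prior shrinks)."""
        series, _ = rw.simulate(
            n_periods=20, groups=2, populations=1e6,
            eta1=np.log(100 / 1e5), tau=0.05, seed=7,
        )
        post = fit(series, ModelSpec(joint=True, chains=2,
                                     draws_per_chain=1200, warmup=600,
                                     seed=2),
                   check_diagnostics=False)
        assert post.corr is not None
        off = post.corr[:, :, 0, 0, 1]
        assert -0.5 < off.mean() < 0.5
        # every retained draw must be a valid correlation matrix
        c = post.corr[:, :, 0]
        np.testing.assert_allclose(c, np.swapaxes(c, -1, -2), atol=1e-12)
        np.testing.assert_allclose(
            np.diagonal(c, axis1=-2, axis2=-1), 1.0, atol=1e-12
        )
        assert np.all(np.linalg.eigvalsh(c) > -1e-12)
        assert np.all(post.tau > 0)

    def test_identical_seed_identical_draws(self):
        series, _ = rw.simulate(10, seed=5)
        spec = ModelSpec(chains=2, draws_per_chain=400, warmup=200, seed=9)
        a = fit(series, spec, check_diagnostics=False)
        b = fit(series, spec, check_diagnostics=False)
        np.testing.assert_array_equal(a.eta, b.eta)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_population_rescaling_shrinks_but_does_not_shift(self):
        """x10 population at the same true rate: posterior SDs shrink and
        means move by less than 3 (original) SDs."""
        spec = ModelSpec(chains=2, draws_per_chain=1000, warmup=500, seed=6)
        small, _ = rw.simulate(12, populations=1e5,
                               eta1=np.log(1e-3), tau=0.0, seed=21)
        big, _ = rw.simulate(12, populations=1e6,
                             eta1=np.log(1e-3), tau=0.0, seed=21)
        ps = fit(small, spec, check_diagnostics=False)
        pb = fit(big, spec, check_diagnostics=False)
        rs, rb = ps.rate_draws(per=1e5), pb.rate_draws(per=1e5)
        assert rb.std(axis=(0, 1)).mean() < rs.std(axis=(0, 1)).mean()
        shift = np.abs(rb.mean(axis=(0, 1)) - rs.mean(axis=(0, 1)))
        assert np.all(shift < 3 * rs.std(axis=(0, 1)))

    def test_joint_requires_two_groups(self):
        series, _ = rw.simulate(8, seed=1)
        with pytest.raises(ValueError, match="2 groups"):
            fit(series, ModelSpec(joint=True, chains=2,
                                  draws_per_chain=100, warmup=50))

    def test_binomial_family_fit(self):
        series, truth = rw.simulate(
            n_periods=10, populations=50000.0, eta1=-3.0, tau=0.03,
            family="binomial", seed=13,
        )
        post = fit(series, ModelSpec(family="binomial", chains=2,
                                     draws_per_chain=800, warmup=400,
                                     seed=3),
                   check_diagnostics=False)
        est = post.rate_draws().mean(axis=(0, 1))
        true_prob = expit(truth.eta[:, 0, 0])
        sd = post.rate_draws().std(axis=(0, 1))
        assert np.all(np.abs(est - true_prob) < 4 * sd + 1e-4)


class TestModelSpecValidation:
    def test_warmup_must_be_less_than_draws(self):
        with pytest.raises(ValueError, match="warmup"):
            ModelSpec(draws_per_chain=100, warmup=100)

    def test_defaults_match_analysis_protocol(self):
        spec = ModelSpec()
        assert (spec.chains, spec.draws_per_chain, spec.warmup) \
            == (4, 6000, 3000)
        assert spec.retained == 3000
        assert (spec.eta1_prior_mean, spec.eta1_prior_sd,
                spec.tau_prior_sd) == (-5.0, 5.0, 1.0)

    def test_bad_family(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec(family="negbin")


def test_hmc_posterior_matches_emcee_oracle():
    """Dual-route check: this package's HMC vs an independent affine-
    invariant ensemble sampler run on the *reference* densities
    (log_prior_density + log_likelihood), compared on posterior means and
    tau quantiles."""
    emcee = pytest.importorskip("emcee")
    series, _ = rw.simulate(
        n_periods=6, populations=2e5, eta1=np.log(5e-4), tau=0.08, seed=17
    )
    y = series.counts[:, 0, 0]
    p = series.populations[:, 0, 0]
    spec = ModelSpec()
    n = 6

    def log_prob(theta):
        eta, lt = theta[:n], theta[n]
        if not -20 < lt < 3:
            return -np.inf
        tau = np.exp(lt)
        return (log_prior_density(eta, tau, spec)
                + log_likelihood(y, p, eta) + lt)

    rng = np.random.default_rng(1)
    nw = 32
    p0 = np.empty((nw, n + 1))
    p0[:, :n] = np.log((y + 0.5) / p)[None, :] + 0.05 * rng.normal(
        size=(nw, n))
    p0[:, n] = np.log(0.08) + 0.1 * rng.normal(size=nw)
    sampler = emcee.EnsembleSampler(nw, n + 1, log_prob)
    sampler.random_state = np.random.RandomState(2).get_state()
    sampler.run_mcmc(p0, 4000, progress=False)
    chain = sampler.get_chain(discard=1000, thin=4)  # (steps, nw, dim)
    eta_ref = chain[..., :n].reshape(-1, n)
    tau_ref = np.exp(chain[..., n].reshape(-1))

    post = fit(series, ModelSpec(chains=4, draws_per_chain=3000,
                                 warmup=1500, seed=3),
               check_diagnostics=False)
    rates_hmc = post.rate_draws().reshape(-1, n)
    rates_ref = np.exp(eta_ref)
    np.testing.assert_allclose(
        rates_hmc.mean(axis=0), rates_ref.mean(axis=0), rtol=0.02
    )
    np.testing.assert_allclose(
        rates_hmc.std(axis=0), rates_ref.std(axis=0), rtol=0.15
    )
    tau_hmc = post.tau.reshape(-1)
    for qt in (0.25, 0.5, 0.75):
        assert np.quantile(tau_hmc, qt) == pytest.approx(
            np.quantile(tau_ref, qt), rel=0.15
        )
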