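# ratewalk

Bayesian random-walk time-series models for disease surveillance.

`ratewalk` is for epidemiologists and public-health analysts who monitor
disease incidence or mortality from registry data — evenly spaced tables of
case counts and populations at risk, optionally stratified by demographic
group and age.  It fits a parsimonious Bayesian time-series model by MCMC
and, because every derived quantity is computed draw by draw, returns
honest credible intervals not just for rates but for percent change,
age-standardized rates, and health-inequality measures.  It is an
alternative to joinpoint-style piecewise-linear trend fitting, which
constrains the trend shape and understates uncertainty by conditioning on a
selected changepoint model.

## Model

For periods *t* = 1..*n* with observed case counts *y<sub>t</sub>* and
populations at risk *P<sub>t</sub>*:

```
y_t ~ Poisson(P_t · exp(η_t))          (or  y_t ~ Binomial(P_t, logit⁻¹(η_t)))
η_t ~ Normal(η_{t−1}, τ²),  t > 1      first-difference (random-walk) prior
η_1 ~ Normal(−5, 5²)                   diffuse for rare events
τ   ~ HalfNormal(1)
```

The latent log-rate η follows a random walk: risk varies smoothly over
time without any assumed functional form.  For *k* related groups the
increments can instead be multivariate normal, **η**<sub>t</sub> ~
Normal(**η**<sub>t−1</sub>, Σ) with Σ = diag(τ)·Corr·diag(τ) and an LKJ
prior on the correlation matrix.

Sampling uses the package's Hamiltonian Monte Carlo implementation
(non-centered parameterization, analytic gradients, windowed step-size and
mass-matrix adaptation), with all chains and independent series advanced in
one vectorized pass.  Convergence is gated on the classic split R-hat
statistic (< 1.01) and the Monte Carlo standard error of each posterior
mean (< 10% of the posterior SD).

From the posterior draws the package computes, per draw and only then
summarized (mean and equal-tailed 95% CI):

- annual percent change APC<sub>t</sub> = 100(R<sub>t</sub>/R<sub>t−1</sub> − 1),
  cumulative percent change, and AAPC over windows of periods;
- directly age-standardized rates SR<sub>t</sub> = Σ<sub>i</sub> w<sub>i</sub>
  R<sub>it</sub> (the 2000 US standard million weights for ages 50–79 ship
  with the package);
- pairwise inequality between a disadvantaged (d) and advantaged (a)
  group: rate ratio R<sub>d</sub>/R<sub>a</sub>, rate difference
  R<sub>d</sub>−R<sub>a</sub>, proportion attributable risk RD/R<sub>d</sub>,
  excess cases RD·P<sub>d</sub>, and their cumulative forms (with
  stratum-wise accumulation for age-standardized comparisons);
- the Theil index T = Σ<sub>j</sub> ω<sub>j</sub> ln(ω<sub>j</sub>/p<sub>j</sub>)
  over groups' burden shares ω and population shares p, with an additive
  between/within decomposition over nested units.

## Worked example

Simulate a 20-year panel for two groups whose true starting rates are 188
and 144 per 100,000, fit the model at the default protocol (4 chains ×
6000 draws, first 3000 discarded as warmup), and summarize:

```python
import numpy as np
import ratewalk as rw
from ratewalk.derived import cumulative_percent_change, aapc
from ratewalk.inequality import pairwise

series, truth = rw.simulate(
    n_periods=20, groups=("black", "white"),
    eta1=np.log(np.array([188.0, 144.0]) / 1e5),
    tau=0.04, populations=np.array([8e5, 2.5e6]),
    population_growth=0.02, seed=2024,
)
post = rw.fit(series, rw.ModelSpec(seed=1))

for g in series.groups:
    c = cumulative_percent_change(post, group=g)[-1]
    print(f"{g} cumulative change: {c.mean:.0f}% ({c.lwr:.0f} to {c.upr:.0f})")

ineq = pairwise(post, group_d="black", group_a="white")
s = rw.summarize(ineq.rd[..., -1], transform=lambda x: 1e5 * x)
print(f"RD 2018: {s.mean:.0f} ({s.lwr:.0f} to {s.upr:.0f}) per 100k")
s = rw.summarize(ineq.cumulative_ec)
print(f"cumulative EC: {s.mean:.0f} ({s.lwr:.0f} to {s.upr:.0f}) cases")
```

prints (posterior means with 95% CIs):

```
black cumulative change: -11% (-16 to -7)
white cumulative change: 11% (7 to 16)
RD 2018: 7 (1 to 14) per 100k
cumulative EC: 3584 (3171 to 4004) cases
```

The cumulative percent change compares each group's 2018 rate with its
1999 rate; the rate difference is the absolute Black–White gap in 2018;
the cumulative excess cases count how many cases over 1999–2018 are
attributable to that gap (here driven by the simulation's persistent
rate difference and growing population).  This run passed the
convergence gates (max split R-hat 1.0025).

The same workflow is available from the shell:

```sh
ratewalk simulate --periods 20 --tau 0.04 --seed 10 --out panel.csv
ratewalk fit --input panel.csv --seed 1 --out run/
```

which writes `rates.csv`, `change.csv`, `diagnostics.csv`, and a
`manifest.json`; exit status 0 means all diagnostic gates passed.

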