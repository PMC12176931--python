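# knotpgm

Bayesian linear–linear piecewise growth models (PGMs) with a **freely
estimated knot location**, for longitudinal researchers who want to
find *when* a developmental trajectory changes phase — and to understand
how that estimate reacts to prior choices and to attrition-style missing
data.

A linear–linear PGM describes each subject's repeated outcomes as

    y_i = Λ(γ) η_i + ε_i,    η_i ~ N(α, Ω_η),    ε_i ~ N(0, diag(σ²)),

where the three growth factors in η are an intercept, a pre-knot slope
and a post-knot slope, and row *j* of the loading matrix is
[1, min(t_j, γ), max(t_j − γ, 0)]. The knot γ — the changepoint on the
study time scale — is a free parameter with either a uniform prior over
the study window or a truncated-normal prior whose center and variance
encode where (and how confidently) a changepoint is expected.

The package provides:

- the model core (loading matrix, implied moments, marginal likelihood);
- a synthetic-data generator with missing-at-random attrition whose
  per-occasion missingness is driven by the standardized first-occasion
  outcome through a logistic model (slope 1.48 by default), with
  decelerated / constant / accelerated schedules reaching 30% or 70%
  at the final wave;
- seven named knot-prior presets (`DIF`, `I-ATK`, `WI-ATK`, `I-PRK`,
  `WI-PRK`, `I-PSK`, `WI-PSK`) that rescale to any time grid;
- a Metropolis-within-Gibbs sampler with data augmentation for missing
  outcomes and rank-normalized split R-hat convergence screening;
- Monte Carlo outcome measures (convergence rate, coverage, average
  bias, RMSE) and a fully seeded factorial study runner (3 sample sizes
  × 7 missing-data levels × 7 priors = 147 cells by default);
- a CLI: `knotpgm simulate | fit | study | evaluate`.

See `docs/methods.md` for the model, priors, sampler and design choices
in detail.

## Worked example

Simulate a 150-subject study from the default population model (knot at
coded time 3 of occasions 0..6, slope change of 0.8 slope-SDs), impose
constant-increase attrition reaching 30% at the last wave, and fit with
the informative prior at the true knot:

```python
import numpy as np
import knotpgm as kp

pop = kp.default_population()
data = kp.generate_complete(pop, n=150, seed=11)
data = kp.apply_mar(data, kp.MissingnessSpec.from_pattern("constant", 0.30), seed=12)
print("missing fraction by occasion:", np.round(data.missing_fraction_by_occasion(), 2))

priors = kp.default_nuisance_priors(kp.knot_prior_preset("I-ATK"))
result = kp.fit(data, priors, kp.MCMCConfig.scaled(seed=13))
print("converged:", result.converged)
print(kp.summarize(result).loc[["gamma", "alpha[1]", "alpha[2]", "alpha[3]"]].round(3))
```

Output:

```
missing fraction by occasion: [0.   0.04 0.09 0.15 0.22 0.27 0.35]
converged: True
             mean  median     sd  ci_lower  ci_upper   rhat
parameter
gamma       2.998   2.979  0.358     2.344     3.718  1.020
alpha[1]   50.684  50.686  0.451    49.802    51.559  1.000
alpha[2]    1.092   1.093  0.103     0.887     1.289  1.002
alpha[3]    1.296   1.297  0.112     1.071     1.520  1.006
```

The knot posterior centers on the generating value 3 with a 95%
credible interval [2.34, 3.72]; the growth-factor means recover
(50, 1.0, 1.4), and every monitored R-hat is below the 1.1 cutoff.
`MCMCConfig.scaled()` is the desk-scale protocol (2 chains, 1,000
burn-in, 4,000 retained); `MCMCConfig()` is the full-scale 4 × 25,000
protocol.

The same analysis runs from the shell on any wide-format CSV (header row
of time codes, one row per subject, empty cell = missing):

```bash
knotpgm simulate --n 150 --pattern constant --terminal-prop 0.3 --seed 11 --out study.csv
knotpgm fit study.csv --priors DIF,I-ATK,WI-ATK --seed 13
```

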