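# cephgrowth

Growth modeling for linear craniofacial traits: Bayesian multilevel
double-logistic fits to longitudinal cephalometric data, and a
cross-sectional resampling framework for asking how well single-visit
samples recover longitudinal growth standards and milestones.

## The problem

Dense longitudinal growth data — repeated radiographs of the same children
across ages — are the gold standard for estimating growth curves, growth
standards (age-specific percentile intervals), and milestones such as the
adolescent peak growth velocity that orthodontic treatment timing depends
on. But serial radiography is rarely feasible; most available samples are
cross-sectional, one observation per person. This package implements the
modeling pipeline needed to (a) fit population growth curves to either
kind of data and (b) quantify, by simulation and resampling, how much is
lost when only cross-sectional data are available.

Because real serial cephalometric data carry personal health information,
the package ships a synthetic-data generator that reproduces the
statistical structure of a large historic growth consortium (per-sex
sample of ~959 individuals, 2–22 visits each with a median of 9,
between-individual SD ~3 mm, measurement error ~0.87 mm).

## The model

Trait size (an inter-landmark distance in mm) follows a double-logistic
curve in age, the sum of a prepubertal and an adolescent phase:

    y(age) = a1 / (1 + exp(-b1 (age - c1))) + (f - a1) / (1 + exp(-b2 (age - c2)))

with `f` the asymptotic size at growth cessation, `a1` the prepubertal
asymptote, `b1`, `b2` phase rate parameters (restricted positive so growth
is monotone), and `c1`, `c2` the ages at maximal phase growth rate. The
longitudinal model is hierarchical:

    y_i  ~ Normal(mu_i, sigma)
    mu_i = double_logistic(age_i) + a_ID[i]
    a_ID ~ Normal(0, sigma_ID)

with Normal priors on the curve parameters (trait-specific means elicited
by a population-based global optimizer; fixed SDs of 2 mm, 0.2 /y and 1 y
for sizes, rates and ages) and Exponential(0.25) priors on `sigma` and
`sigma_ID`. The cross-sectional model is identical minus the individual
intercept — which is exactly why it cannot separate measurement error from
phenotypic variation. Growth rate is the closed-form first derivative of
the curve; peak growth velocity (PGV, mm/y) and its age (aPGV, years) are
its maximum over an adolescent age window.

Sampling uses an affine-invariant ensemble MCMC over the marginal
likelihood (individual intercepts integrated out analytically and
recovered by exact conditional draws); a MAP mode maximizes the same
posterior density for large resampling designs.

## Worked example

```python
import numpy as np
from cephgrowth import (PopulationConfig, generate_population, elicit_prior_means,
                        GAConfig, FitConfig, fit_longitudinal, find_milestones)

# 1. simulate a longitudinal study population (150 individuals)
config = PopulationConfig(n_individuals=150, seed=11)
data = generate_population(config)
print(f"{data.n_individuals} individuals, {data.n_observations} radiographs")

# 2. elicit trait-specific prior means from the pooled scatter
prior = elicit_prior_means(data.table["age"], data.table["value"], GAConfig(seed=1))
print("prior mean for f: %.1f mm (95%% interval %.1f-%.1f mm)"
      % (prior.means.f, *prior.central_interval("f")))

# 3. fit the multilevel longitudinal model (MAP here; mode="mcmc" for full posteriors)
post = fit_longitudinal(data, prior, FitConfig(mode="map"))
params = post.median_params()
print("asymptote f = %.1f mm, residual SD = %.2f mm, individual SD = %.2f mm"
      % (params.f, post.flat("sigma")[0], post.flat("sigma_id")[0]))

# 4. growth milestones over the adolescent window
ms = find_milestones(params, (10.0, 20.0))
print("PGV = %.2f mm/y at aPGV = %.1f y (%s phase)" % (ms.pgv, ms.apgv, ms.phase))
```

Output:

```
150 individuals, 1365 radiographs
prior mean for f: 101.6 mm (95% interval 97.6-105.5 mm)
asymptote f = 101.4 mm, residual SD = 0.87 mm, individual SD = 3.18 mm
PGV = 1.80 mm/y at aPGV = 11.2 y (adolescent phase)
```

The fitted residual SD (0.87 mm) is the radiograph-level measurement
error, separated from the 3.2 mm of between-individual size variation —
the separation only longitudinal data make possible. The adolescent spurt
peaks at ~1.8 mm/y around age 11, plausible for a cranial-base distance
in females.

The same pipeline is scriptable from the shell:

```sh
cephgrowth simulate --out run/sim
cephgrowth elicit-priors --data run/sim/dataset.csv --out run/prior
cephgrowth fit --data run/sim/dataset.csv --prior run/prior/prior.yaml --mode map --out run/fit
cephgrowth resample --data run/sim/dataset.csv --prior run/prior/prior.yaml \
    --sizes 50,200,full --reps 20 --mode map --out run/exp
cephgrowth compare --experiment run/exp --reference run/fit/posterior.csv --out run/cmp
```

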