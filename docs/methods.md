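# Methods

## Model

A linear craniofacial trait (mm) is modeled as a double-logistic function
of age: two additive logistic phases, prepubertal and adolescent,

    y(age) = a1 / (1 + e^{-b1 (age - c1)}) + (f - a1) / (1 + e^{-b2 (age - c2)}),

giving a smooth curve with directly interpretable coefficients: sizes
`f`, `a1` (mm), rates `b1`, `b2` (1/y), timing `c1`, `c2` (y). With
`b1, b2 > 0` and `f >= a1` the curve increases monotonically and `f` is
the size at growth cessation. `f >= a1` is *not* hard-enforced in the
parameter type (only a warning), because fitted posteriors may wander
there transiently; monotonicity guarantees are suspended in that region.

The longitudinal observation model is hierarchical: observation `i` of
individual `j` is

    y_i ~ Normal(mu_i, sigma),   mu_i = double_logistic(age_i) + a_j,
    a_j ~ Normal(0, sigma_ID),

so `sigma` is radiograph-level measurement error and `sigma_ID`
between-individual size variation. The cross-sectional model drops `a_j`
and `sigma_ID`; with one observation per person the two variance sources
are confounded and the cross-sectional `sigma` estimates the total
apparent SD `sqrt(sigma^2 + sigma_ID^2)`. This confounding is asserted as
a test invariant, not just narrated.

Priors: Normal on each curve parameter with trait-specific means and
fixed SDs (2 mm for `f`, `a1`; 0.2 /y for `b1`, `b2`; 1 y for `c1`,
`c2`), truncated at zero for the rates; Exponential(0.25) on `sigma` and
`sigma_ID`. Only the prior means are free; they are elicited from the
data (below).

## Posterior computation

The individual intercepts are Gaussian and enter linearly, so they are
integrated out analytically: individual `j`'s observation vector is
multivariate normal with covariance `sigma^2 I + sigma_ID^2 J`, whose
log-density follows from the rank-one Woodbury identity in O(n_j) per
individual. MCMC therefore runs in the 8-dimensional population-parameter
space using an affine-invariant ensemble sampler. Defaults: 4 chains x 8
walkers, 10,000 ensemble iterations, 50% warmup, thin 5, walker starting
values drawn from the priors. Walkers are grouped round-robin into the
configured chain count for diagnostics. Intercept draws are recovered
afterwards by exact conditional Normal sampling (thinned to <= 200 draws
per chain to bound memory), so the joint draws are from the full
hierarchical posterior.

Convergence gate: rank-normalized split R-hat < 1.01 and bulk ESS >= 400
for every scalar parameter. A failing fit is returned flagged, never
silently.

MAP mode maximizes the identical log posterior density (scales searched
in log-space, no Jacobian term, so the optimum is the natural-scale
density mode) with an L-BFGS-B pass warm-started from a bounded nonlinear
least-squares curve fit. MAP is the workhorse for resampling designs with
hundreds of fits; its output is a one-draw posterior, which prediction
utilities treat as a point mass.

## Prior elicitation

Prior means are the least-squares double-logistic fit to the pooled
(age, value) scatter, found by differential evolution — a population-based
evolutionary global optimizer (population 25 x 6, up to 200 generations,
seeded). Two reparameterizations keep the search identified: `f = a1 + df`
with `df >= 0` (candidates are monotone curves; the unconstrained problem
has a spurious non-monotone basin with a negative adolescent phase) and
`c2 = c1 + gap` with `gap >= 0.5` y (phases stay ordered). The landscape
also contains a phase-role-swapped local basin, so the search runs 4
independent seeded restarts and keeps the best; on noiseless data the
generating parameters are recovered to machine precision. The ordering
constraint applies to elicitation only — posterior sampling imposes
neither `c1 < c2` nor `f >= a1`.

Prior predictive adequacy is checked by simulation: curves drawn from the
priors alone should stay on the outcome scale (the automated form: >= 90%
of draws within [0, 2 Pr_f] across the age grid).

## Synthetic populations

The generator is the observation model run forward. Defaults emulate a
large per-sex historic growth study:

| setting | default | rationale |
|---|---|---|
| individuals | 959 | per-sex scale of the emulated consortium |
| visit model | enrollment uniform in the lower third of [4, 22] y; annual visits; first follow-up guaranteed; later visits retained with p = 0.906 | yields median 9 visits per individual, range within [2, 22] |
| sigma | 0.87 mm | median cephalometric measurement error |
| sigma_ID | 3 mm | plausible between-individual SD for a ~100 mm trait |
| truth curve | f = 101, a1 = 88 mm; b1 = 0.9, b2 = 0.55 /y; c1 = 3, c2 = 11.5 y | adult size ~100 mm; adolescent velocity peak ~1.8 mm/y near 11.4 y |

The truth rates were chosen so that an *interior* adolescent velocity
maximum exists inside the observable age range: with a substantially
slower prepubertal rate the prepubertal velocity tail dominates
everywhere above age 4 and total velocity decreases monotonically — then
"age at peak growth velocity" degenerates to a window boundary and the
milestone analysis measures nothing. With b1 = 0.9 the prepubertal phase
contributes 52% of total velocity at age 8, 24% at 9 and 9% at 10, and
the global velocity maximum on [10, 20] y is the adolescent peak
(~1.83 mm/y at 11.36 y).

What the generator does **not** emulate: landmark coordinates and
digitization error structure, radiographic enlargement, multi-trait
correlations, secular trends across source studies, or non-Gaussian
residuals. Passing tests therefore demonstrate the statistical machinery
under the model's own assumptions, not robustness to their violation.
Optional per-observation missingness (default 0) emulates trait-specific
full-sample size variation; individuals falling below two retained
observations are excluded, mirroring the inclusion rule.

## Resampling experiment

A cross-section draws n individuals without replacement, then one
observation uniformly at random from each individual's series, with no
age or series-length conditions; each individual is equally likely to be
included regardless of visit count (asserted as an inclusion-frequency
invariant). The full design is 200 replicates at
n in {5, 10, 20, 50, 100, 200, 300, 500, full}; replicate seeds are a
deterministic function of (master seed, size, replicate), so any design
subset reproduces identically and results are independent of execution
order. Failed fits are recorded with their reason, never dropped.

Replicates at one size are aggregated three ways: the distribution of
per-replicate posterior medians, the parameter-wise median across
replicates ("median cross-sectional model"), and the pointwise median of
predicted curves — the latter two are both exposed because the choice of
aggregation is genuinely open; they coincide closely in practice. Pooled
draws across replicates feed percentile-band construction.

## Comparison metrics

All comparisons use the age grid 5–20 y at 0.25 y steps (the trait is
observable from age 4; the grid avoids edge extrapolation). Mean absolute
difference (MAD) is computed between replicate *median* curves and the
longitudinal median curve, pointwise then averaged over the grid.
Milestones are extracted on the window [10, 20] y — chosen so the window
starts after the prepubertal peak region (prepubertal velocity share < 10%
at the window start for the default population); an earlier start lets a
heavy fitted prepubertal tail capture the argmax at the boundary, turning
aPGV into a boundary artifact. The milestone finder itself takes an
explicit window: a 0.01 y grid scan with bounded local refinement within
one grid step, ties broken toward the older age.

## Scaled analysis sizes

The shipped end-to-end analyses (test suite and acceptance script) use 20
map-mode replicates at n = 100, 200 and full on the default 959-individual
population, a MAP longitudinal reference, and a 4-chain MCMC fit (6,000
ensemble iterations) on a 100-individual population for measurement-error
recovery. These sizes were chosen as the smallest at which the replicate
aggregates are stable; the full 200-replicate MCMC design is available
through the same interfaces.

## Known limitations

- The ensemble sampler explores the 8-parameter marginal space well, but
  heavily multimodal posteriors (tiny n, diffuse priors) can trap
  walkers; such fits fail the convergence gate and are flagged.
- MAP point estimates understate uncertainty; mean-curve bands from MAP
  fits collapse to the fitted curve by construction.
- The aPGV of a fitted curve is ill-defined when the velocity has no
  interior maximum in the window; the milestone record's `phase` field
  and the window choice make this explicit rather than hiding it.
- Elicited prior means reuse the data being fit (empirical-Bayes style),
  as in the emulated workflow; the fixed prior SDs keep this mildly
  regularizing rather than double-counting strongly.
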