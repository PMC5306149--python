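# Methods

## The model

`seasongamm` models temporal host specificity in a brood-parasite system:
European bitterling (*Rhodeus amarus*) lay eggs in the gills of living
unionid mussels, and a field survey scores each collected mussel (enclosed in
a mesh bag for 24 h) for presence/absence of released embryos. The response
for mussel *i* in oxbow lake *j* and year *k* is modelled as

    Bitterling_ijk ~ Bernoulli(pi_ijk)
    logit(pi_ijk)  = beta + Species_ijk + f_s(Day_ijk) + Oxbow_j + Year_k
    Oxbow_j ~ N(0, sigma_Oxbow^2),  Year_k ~ N(0, sigma_Year^2)

with a categorical host-species effect (four levels: *Anodonta anatina*,
*A. cygnea*, *Unio pictorum*, *U. tumidus*), one smooth season-day effect
per species, and exchangeable lake and year intercepts. Day counts from
1 May, the designated start of the spawning season.

### Smoothers

Each f_s is an O'Sullivan spline: a cubic B-spline with the integrated
squared second derivative as penalty, Omega[j,k] = ∫ B_j'' B_k''. Five
interior knots sit at equally spaced quantiles of that species' observed
days ("knot position permitted to vary" is read as data-driven placement,
not as knots sampled in the MCMC — there is no standard sampler for free
knots in this workflow). Boundary knots extend 0.1% of the day range beyond
the observed min/max to avoid edge degeneracy. Five means five *interior*
knots (the natural reading; a different count is one argument away).

The penalty has a two-dimensional null space (constant + linear), so the
basis is reparameterized through the eigendecomposition Omega = U diag(d) Uᵀ
into an unpenalized linear column plus Z = B U₊ diag(d₊)^{-1/2}, whose
coefficients get an iid N(0, tau_s²) prior — the mixed-model form in which
a smoothing parameter is a variance ratio. Eigenvalues below 1e-10 × max(d)
are classified as null space; a null-space dimension other than 2 raises an
error rather than silently proceeding. The penalty integral is evaluated by
4-point Gauss–Legendre per inter-knot interval, which is exact for the
piecewise-quadratic integrand of cubic splines.

Identifiability: within each species' rows the linear column and every Z
column are mean-centered, so the species dummies alone carry each species'
level and smoothers are deviations; smoother curves are therefore only
comparable as *shapes*, and "total preference" contrasts add the species
effects back (both variants are exposed; the combined one is the default
because the survey narrative concerns total preference).

### Priors

"Diffuse or non-informative" is made concrete as N(0, 100²) on all fixed
effects (intercept, species dummies, per-species linear day slopes) and
Uniform(0, 20) on every standard deviation (lake, year, and one per-species
smoother SD). Both are configurable on `build_spec`. These are the common
defaults of the JAGS-style workflow this package mirrors (dnorm(0, 1e-4),
dunif(0, 20)); their diffuseness has visible consequences for weakly
identified directions — see *Calibration of the posterior-predictive check*.

### Sampling

Inference is by Pólya-Gamma data augmentation: omega_i ~ PG(1, eta_i) makes
the Bernoulli-logit likelihood conditionally Gaussian, so all coefficients
update as one joint Gaussian block (a single Cholesky solve per sweep —
there is no tuning, no acceptance rate, and mixing is far better than
one-at-a-time Metropolis). Each variance has a conjugate update: with a
uniform prior on the SD, tau² | u is inverse-gamma((q−1)/2, ‖u‖²/2)
truncated to (0, 20²), sampled by inverse CDF on the precision scale.

The PG(1, z) sampler is implemented in-package (numba-compiled scalar
kernels) with Devroye's alternating-series rejection method: a mixture of a
truncated exponential (right of 0.64) and a truncated inverse-Gaussian
proposal, thinned by the partial-sum acceptance test. It is verified against
the closed form E[PG(1,z)] = tanh(z/2)/(2z) and, end to end, against the
logistic-regression MLE and an independent JAGS fit of the identical model.

Chains are independent, with per-chain RNG streams spawned from a master
seed (all seeds kept below 2³¹); runs are bit-reproducible for a fixed
(spec, settings). The survey analysis schedule — 3 chains, 50,000 burn-in,
500,000 iterations thinned by 10 — is read per chain (50,000 retained draws
per chain); this package's tests and the acceptance script use reduced
schedules (below). A `prior_only` mode switches the likelihood off (the
coefficient update then draws exactly from the prior), used to verify the
sampler recovers its own prior.

### Diagnostics and posterior products

Convergence uses the classic (non-split) Gelman–Rubin PSRF,
sqrt([W(n−1)/n + B/n]/W), matching the cited workflow; split-R̂ is a flag.
Effective sample size uses Geyer initial-positive-sequence truncation.

Curves and contrasts are computed draw-by-draw and summarized pointwise by
equal-tailed 2.5/97.5 percentiles (matching standard Gibbs summaries; no
simultaneous bands, as in the original figures). Probability curves apply
the inverse logit per draw — never to the posterior-mean linear predictor —
with lake/year intercepts at zero (population level); a Monte-Carlo
marginalized variant integrates them over their fitted N(0, sigma²) laws.
A grid point is "important" when its 95% interval excludes zero. The default
grid is 100 equally spaced days over the species' observed range, and
extrapolation beyond the fitted range raises rather than extrapolates.

### Model checks

The posterior-predictive check simulates, per retained draw, a replicate
response vector from the fitted probabilities and compares Pearson-χ²
discrepancies: overall probability = P(T(y_rep) > T(y_obs) | data). The
discrepancy function is pluggable (Pearson-χ² is the default, standard in
this workflow); per-observation replicate frequencies are reported
alongside. Model comparison uses DIC (pD = D̄ − D(θ̄)), with WAIC as an
alternative.

**Calibration of the posterior-predictive check.** On data simulated from
the model's own generating process at n ≈ 2000, the overall probability
centres near 0.1–0.25, not 0.5. This is a property of the procedure, not an
implementation artefact: fitting the identical design with JAGS yields
matching posteriors and the same low p-value on the same data. The
mechanism: the Pearson discrepancy of the *observed* data is inflated by
posterior spread of the fitted probabilities (≈ Σ(π_draw − π_true)²/v),
while the *replicate* discrepancy is simulated from the same draw and is
immune to it; with ~50 parameters under genuinely diffuse priors — flexible
per-species smoothers and a rare-event species level — that spread is
substantial. Omnibus Bayesian p-values are known not to be uniform; users
should read values well below 0.5 on rich Bernoulli models with diffuse
priors as expected behaviour, and values near 0 or 1 as misfit.

Residual diagnostics pool identical-covariate observations into binomial
cells before computing the dispersion statistic (Σ cell Pearson residuals² /
(cells − pD)): a single 0/1 response carries no overdispersion information,
but dependence between replicate observations is visible at the cell level.
The residual-vs-day trend is summarized as the max |cubic polynomial fit|.

## Validation GLMs

The dissection validation (54 mussels bagged, then dissected) and the
host-abundance stability check are ordinary GLMs, fitted in-package by IRLS
with canonical links (log/logit), convergence at relative deviance change
< 1e-10 or 50 iterations, expected-Fisher standard errors evaluated at the
MLE, and separation reported as a diagnostic error carrying the last
iterate. The reported generalised R² is the deviance ratio 1 − D/D₀ (a
squared-correlation variant is a flag). The abundance model uses number /
total with the all-species total as denominator (the literal "all other
species" denominator could exceed 1 and is not implemented as default) and a
single numeric lake×year product covariate matching the one-row-per-species
summary shape; an additive lake + year variant is a flag. The printed
dissection coefficients (−2.38 + 0.26·Dissected; 1.05 + 0.01·Dissected) are
used as generator defaults and prediction fixtures, never as fit targets —
the raw 54-pair data were not deposited.

## Synthetic data

`generate_survey` draws surveys from a known GAMM: per-species Gaussian-bump
smoothers (centered over the design days to match the fitted model's
identifiability), species effects, and lake/year intercepts drawn once per
realization. Defaults emulate the published survey: intercept −1.4; species
effects anatina 0, pictorum +1.5, tumidus −0.1, cygnea −2.5; bumps peaking
near day 40 (infection greatest between days 35–45); sigma_Oxbow = 0.5,
sigma_Year = 0.3; 13 lakes, 3 years, 9 sampling days per year (27 discrete
dates); species mix 0.41/0.23/0.20/0.16. These were set once from the
published marginal prevalences (0.28/0.05/0.69/0.29 released in the analysis
subset) and its qualitative narrative; the near-separating −5-scale cygnea
effect printed in the published contrast table emerges in *fitting* (the
posterior drifts far negative with a wide interval) without being put into
the generator. What the generator does NOT emulate: within-lake spatial
structure, repeated measures of individual mussels, day-by-lake sampling
imbalance, or any behavioural host-choice dynamics — so passing recovery
tests demonstrate statistical correctness of the machinery, not realism of
those survey features.

`generate_dissection_pairs` draws a zero-inflated-Poisson embryo burden and
release presence from the printed logit coefficients; released and dissected
counts are disjoint (released embryos left the gill before dissection), so
neither bounds the other.

`build_survey_fixture` deterministically lays out 1889 records matching every
printed margin (monthly totals 501/532/751/105; species totals
773/430/371/315; post-exclusion species counts 723/385/339/285 with
202/20/233/82 positives; lakes 3 and 11 only in July so the exclusions
remove exactly 52 + 105 records). Allocation beyond the printed margins is a
documented free choice: largest-remainder apportionment with round-robin
lake/year/day assignment, August and excluded-lake records carrying no
releases. The seed permutes only the record order.

## Problem sizes

Default schedules used by the shipped tests and the acceptance script (all
chosen as a deliberate compromise between Monte-Carlo error and runtime on a
single CPU):

* acceptance fit: n = 2000 survey, 3 chains × (5,000 burn-in + 50,000
  iterations, thin 10) → 15,000 retained draws; max PSRF ≈ 1.001 in ~4 min.
* shared test fit: n = 1200, 3 chains × (2,000 + 10,000, thin 10).
* coverage study: 100 replicates at n = 2000 with 1 chain × (500 + 1,500,
  thin 3) each; short chains widen intervals slightly, which is conservative
  for coverage.
* JAGS cross-check: n = 250, shared smoother, 6,000 iterations.

## Known limitations

* The Pearson-discrepancy Bayesian p-value is not calibrated to 0.5 under
  rich models with diffuse priors (see above); it remains useful as a
  misfit alarm, not as a goodness certificate.
* Equal-tailed credible intervals under quasi-separation (a species with a
  handful of positives and a diffuse prior) are strongly asymmetric and do
  not have frequentist coverage for that parameter; the package reports them
  faithfully rather than reparameterizing them away.
* Pointwise bands only; no simultaneous curve bands.
* The Gibbs sampler assumes the Bernoulli-logit link throughout; no probit
  or complementary-log-log variants.
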