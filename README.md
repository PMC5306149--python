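# seasongamm

Bayesian Bernoulli GAMMs for seasonal host-specificity surveys.

European bitterling (*Rhodeus amarus*) are brood parasites of freshwater
mussels: females lay eggs in the gill chamber of living unionids, which pay
for it in growth, oxygen stress and gill damage. Which of the four host
species (*Unio pictorum*, *U. tumidus*, *Anodonta anatina*, *A. cygnea*)
gets used — and **when** in the spawning season preference shifts between
them — is the scientific question this package's model answers from
presence/absence survey data.

## The model

For mussel *i* in oxbow lake *j* and year *k*, with `Bitterling` the binary
embryo-release indicator and `Day` counted from 1 May:

```
Bitterling_ijk ~ Bernoulli(pi_ijk)
logit(pi_ijk)  = beta + Species_ijk + f_s(Day_ijk) + Oxbow_j + Year_k
Oxbow_j ~ N(0, sigma_Oxbow^2),   Year_k ~ N(0, sigma_Year^2)
```

Each species gets its own smoother `f_s`, an O'Sullivan penalized spline
(cubic B-splines, integrated-squared-curvature penalty, five interior knots
at day quantiles) in mixed-model form, so the whole model is a hierarchical
Bayesian logistic regression. Sampling is by exact Pólya-Gamma data
augmentation — every coefficient updates as one joint Gaussian block, no
tuning — with conjugate truncated updates for the variance parameters.
Posterior products are the survey-analysis staples: per-species seasonal
curves with 95% credible bands, pairwise smoother contrasts that locate the
season window where one host is significantly preferred, baseline-recoded
species contrast tables, Gelman–Rubin convergence checks, posterior
predictive checking and DIC model comparison. Supporting pieces — the
dissection-validation GLMs, host-abundance GLMs, exclusion filters and
tabulations, and synthetic-survey generators with known ground truth — are
all included. See `docs/methods.md` for the full model account.

## Worked example

```python
import seasongamm as sg

truth = sg.TruthConfig(n=1000, seed=11)        # known ground truth
records, _ = sg.generate_survey(truth)
spec = sg.build_spec(records, baseline="anatina")
draws = sg.sample_posterior(
    spec, sg.McmcSettings(n_chains=3, burn_in=1000, iterations=5000,
                          thin=10, seed=42))
print(f"max PSRF: {sg.convergence_report(draws).max_psrf:.3f}")
print(sg.species_contrast_table(draws, spec, baseline="anatina")
        .rows.round(2).to_string(index=False))
```

prints (values vary slightly with seeds; short chains here, so the PSRF is
not yet at its long-run level):

```
max PSRF: 1.085
         parameter   mean  lower95  upper95  important
intercept[anatina]  -1.34    -2.22    -0.38       True
   species[cygnea] -13.41   -44.11    -3.06       True
 species[pictorum]   1.19     0.80     1.61       True
  species[tumidus]  -0.19    -0.83     0.38      False
        sigma_lake   0.53     0.25     0.94      False
        sigma_year   0.51     0.01     2.90      False
```

Read: relative to the *A. anatina* baseline, *U. pictorum* is infected
significantly more (logit contrast +1.2, CrI excludes 0 → `important`),
*U. tumidus* indistinguishably, and *A. cygnea* far less — its huge
negative contrast with an extreme lower bound is the signature of a
quasi-separated rare-event level (only ~2% of cygnea records are positive),
faithfully reflected in the wide interval. `smoother_contrast` then
resolves *when* in the season such preferences hold. The `examples/`
scripts walk each capability: filtering/tabulation, the spline basis,
fitting, curves and contrasts, model checks, and the validation GLMs.

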