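# mzipmod

Marginalized zero-inflated Poisson (MZIP) regression and moderation
analysis for zero-inflated count outcomes in two-arm randomized trials.

The package is built for the analysis pattern of brief-alcohol-intervention
trials in college students: a "drinks in a typical week" count outcome with
excess zeros, randomization to a brief motivational intervention (BMI) or a
personalized feedback intervention (PFI), and the question of whether a
baseline binary moderator — here, any drinking during the senior year of
high school — changes which intervention works better. It is equally usable
for any trial with a zero-inflated count outcome and a binary effect
modifier.

## The model

The outcome follows the zero-inflated Poisson mixture

```
Y_i = 0               with probability pi_i        (structural zero)
Y_i ~ Poisson(mu_i)   with probability 1 - pi_i
```

with `logit(pi_i) = z_i'gamma`. The conventional ZIP links the Poisson
component, `log mu_i = x_i'beta_ZIP`, so its coefficients describe only the
latent drinker class. The **marginalized** ZIP links the overall mean of
everyone instead,

```
nu_i = E(Y_i) = (1 - pi_i) * mu_i,     log nu_i = x_i'beta,
```

so `exp(beta_j)` is a population **rate ratio** (RR) and `exp(gamma_j)` an
**odds ratio** (OR) for being a structural (non-drinking) zero. The
moderation pipeline fits the full model with a moderator-by-arm interaction
in both submodels, trims the interaction if its overall-mean Wald test is
nonsignificant, reports stratum-specific intervention RRs
(`e^{beta_arm}` and `e^{beta_arm + beta_int}`), and produces marginally
standardized (g-computed) cell means for the four moderator-by-arm cells
with nonparametric bootstrap percentile 95% intervals.

A synthetic-study generator emulates the motivating trial (n = 348, ~50/50
randomization, 80% moderator prevalence, trial-calibrated MZIP effect
sizes, 2% missing moderator values), so the whole pipeline is testable
without any external data. See `docs/methods.md` for the estimation
details, generator calibration, and known limitations.

## Worked example

```python
import mzipmod as m

table = m.generate_study(m.GeneratorConfig(seed=123))       # synthetic trial
report = m.run_moderation_analysis(table, "4m", bootstrap_B=300, seed=0)
print(report.summary_text())
```

```
Moderation analysis, 4m follow-up
  analyzed n = 343 (5 excluded for missing moderator)
  interaction Wald p = 0.0095 (retained at alpha = 0.05)
  RR(BMI vs PFI | no HS drinking)  = 1.44 (44% higher mean drinks)
  RR(BMI vs PFI | HS drinking)     = 0.90 (10% lower mean drinks)
  g-computed cell means (bootstrap 95% CI):
    hs_drink=0 arm=0: 2.86 [2.18, 3.71]
    hs_drink=0 arm=1: 4.13 [3.20, 5.13]
    hs_drink=1 arm=0: 5.63 [4.88, 6.26]
    hs_drink=1 arm=1: 5.06 [4.50, 5.66]
```

Reading this: 5 of 348 simulated participants lacked the moderator and were
excluded. The interaction is significant, so the model is not trimmed.
Among students with no high-school drinking history, BMI recipients drink a
44% *higher* typical-week mean than PFI recipients at 4 months; among
students who drank in high school, a 10% *lower* mean — close to the
generating rate ratios of 1.49 and 0.91. The four cell means marginalize
each counterfactual moderator/arm setting over the observed covariate
distribution; their within-stratum ratios equal the coefficient-product
RRs exactly (a property of the log link).

The same analysis is available from the shell:

```bash
mzipmod simulate --n 348 --seed 123 --out study.csv
mzipmod moderate --data study.csv --wave 4m --bootstrap 300 --seed 0 \
    --out-json report.json --plot cells.png
mzipmod fit --data study.csv --wave 15m --trimmed --out-table coefs.csv
mzipmod recover --wave 4m --n 1000 --replicates 200 --out recovery.csv
```

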