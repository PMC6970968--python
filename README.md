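# cancertrends

Estimation machinery for national and subnational childhood-cancer (ages
0–14) incidence from an incomplete case registry, written for
epidemiologists and biostatisticians who need the full path from raw
records to reportable measures: registry curation (duplicate removal,
imputation, completeness correction), a two-stage age-spatiotemporal
incidence model with simulation-based uncertainty, an overdispersed
multinomial cause split, and the derived measures — age-standardised rates
(ASR), annual percent change (APC), decomposition of case-count change,
mortality-to-incidence ratio (MIR), and provincial disparity. Because real
registries of this kind are confidential, a synthetic-registry generator
with a logged ground truth makes every stage testable end to end.

## The model

Completeness-corrected counts per (province *p*, year *t*, age group *a*,
sex *s*) give rates per 100,000 person-years. Stage 1 is a random-intercept
mixed model fit by REML,

```
ln(rate + floor) = β₀ + β·X(p,t) + δ·t + α_a + γ_s + u_p + ε,
```

with province random intercepts `u_p` and province–year covariates *X*
(wealth index, education years, urbanization). Stage 2 remodels the
residuals by weighted averaging with separable kernels — spatial weight 1
for the same province, ζ for first-order neighbours on the adjacency graph,
0 otherwise; `exp(−|Δt|/λ)` in time; `exp(−ω·|Δa|)` in age-midpoint
distance — and the estimate is `exp(fitted + smoothed residual) − floor`.
95% uncertainty intervals come from a Poisson parametric bootstrap of the
aggregated counts through the whole estimator. Cause groups are split with
a Dirichlet-multinomial logit model (concentration φ for overdispersion,
MAP estimation). APC is `100·(e^β̂ − 1)` from OLS of ln(rate) on year; ASR
is direct standardisation against the 2016 national age structure;
case-count change decomposes into growth, aging and rate-change components
through two hypothetical populations. Details and all defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the full pipeline on a synthetic registry at the default study
conditions (31 provinces, 1990–2016, ~2,000–2,400 cases/year, completeness
rising from 0.22 to 0.75, injected duplicates and missing fields):

```python
from cancertrends.pipeline import run_pipeline
import pandas as pd

out = run_pipeline({"seed": 11,
                    "curation": {"n_imputations": 3},
                    "model": {"n_draws": 20}}, "run1")
print(pd.read_csv(out / "table1_national.csv").query("sex == 'both'").round(2))
```

```
     age  sex  new_cases_first  new_cases_last  apc_cases  rate_first  rate_last  apc_rate
Under 15 both          2077.43         1766.45      -0.33        8.77       9.21      0.49
      <1 both           116.92           99.82       0.24        7.40       7.80      1.05
     1-4 both           437.40          350.02      -0.58        6.92       6.84      0.23
     5-9 both           692.48          592.47      -0.32        8.77       9.26      0.50
   10-14 both           830.63          724.14      -0.28       10.51      11.32      0.53
```

New cases fall (APC −0.33%/yr) while the age-standardised rate rises
(+0.49%/yr) — the signature of a shrinking child population with rising
age-specific incidence, which the decomposition quantifies
(`decomposition.csv`: growth −19.0%, aging 0.0%, rate change +4.1%, total
−15.0%). The national MIR series (`mir_national.csv`) falls from 0.93 in
1990 to 0.26 in 2016, recovering the generator's 0.25 end/start schedule,
and `table3_provinces.csv` lists the lowest/highest-ASR province per age
and sex with recentred bootstrap intervals. The same stages are available
from the shell:

```bash
cancertrends run-all --seed 11 --out run1
cancertrends validate population=run1/population.csv cube=run1/cube_corrected.csv
```

Single measures work standalone, e.g. the trend in a two-point case series:

```python
import cancertrends as ct
ct.apc({1990: 2478, 2016: 2086}).apc_percent   # -0.66 (%/yr)
```

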