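# Methods

`cancertrends` estimates national and subnational childhood-cancer (ages
0–14) incidence from an incomplete, noisy case registry, splits it into
cause groups, and derives the summary measures used in descriptive cancer
epidemiology. This note documents the models, their assumptions, the
numerical choices, and what the synthetic test bed does and does not show.

## Registry curation

Raw records carry free-text identity fields (first name, surname, parent
name, address) and analytic fields (sex, age, province, diagnosis year,
cause code).

**Duplicate removal.** Records are blocked on the analytic key
(year, province, sex, age group, cause); within a block, two records merge
when the Levenshtein distance between their normalised name strings
(lowercased, punctuation stripped, whitespace collapsed) is at most
`max_edit_fraction` (default 0.2) of the longer string. Merging is closed
transitively with union–find and the earliest `record_id` survives. Names
are deliberately excluded from the blocking key — they carry the spelling
noise — and the analytic block bounds both false merges and the cost of the
within-block comparison. Records with no identity information at all are
flagged unlinkable and never merged. Distances are computed with `edlib`;
the test suite checks the whole procedure against an all-pairs pure-Python
dynamic-programming linkage on fixtures of up to 500 records.

**Imputation.** Residual missing categorical analytic fields are filled by
hot-deck draws from the empirical conditional distribution of complete
records given diagnosis year and, where present, sex and province, falling
back to coarser conditioning sets when a cell has no donors. Each of the
`m` imputations draws independently; observed values are never modified.
This is a deliberate simplification of EM-with-bootstrap multiple
imputation: only low-cardinality categorical fields need filling here, and
the hot-deck keeps the procedure transparent and exactly testable (the
pooled imputed distribution must match the observed-complete distribution
in total-variation distance under MCAR).

**Completeness correction.** Registration completeness is anchored at
two calendar years (defaults 0.22 in 2000 and 0.75 in 2010, from an
insurance-registry capture comparison) and interpolated linearly on the
logit scale, flat outside the anchor range, so values stay inside (0, 1].
One national rate per year applies to all strata, and corrected counts are
`raw / completeness(year)` — linear in the counts, so corrections commute
with aggregation.

## Two-stage incidence model

Let `rate = count / person-years × 1e5`. Stage 1 fits, by restricted
maximum likelihood (statsmodels `MixedLM`),

    ln(rate + floor) = β₀ + β·X(p,t) + δ·year + α_age + γ_sex + u_p + ε,

with province random intercepts `u_p` and optional province–year covariates
(wealth index, education years, urbanization). A single-province input
degenerates to ordinary least squares with `u ≡ 0`.

**The rate floor.** Zero-count cells need a floor inside the logarithm. A
fixed floor far below the observable rate scale makes zero cells
catastrophically informative: at registry sparsity (often well under ten
expected cases per province–year–age–sex cell) the resulting bias varies
with province size and scrambles provincial comparisons. The default is
therefore *adaptive*: half of the year's count quantum per person-year.
Completeness-corrected counts are integer multiples of `1/completeness`, so
the smallest positive count in a year recovers that quantum `q`, and the
floor `0.5·q/PY×1e5` is exactly the classical `ln(N + ½)` continuity
correction expressed on the corrected-rate scale. This restores reliable
province ranking (rank correlation ≈ 0.9 on synthetic registries at default
conditions) while keeping the model linear. A fixed numeric floor remains
available (`floor=0.01`) and is used in tests of the algebraic identities,
where its exact value is irrelevant.

**Stage 2: age-spatiotemporal residual smoothing.** Residuals
`r(c) = observed − fitted` are remodelled as weighted averages over all
same-sex cells with separable weights

    w = w_space × w_time × w_age,
    w_space = 1 (same province), ζ (first-order neighbour), 0 (otherwise),
    w_time  = exp(−|Δt|/λ),
    w_age   = exp(−ω·|Δa|)   (Δa between age-group midpoints 0.5, 3, 7.5, 12.5).

Only first-order neighbours on the province adjacency graph borrow spatial
strength. The smoothed value is a convex combination (the self-weight is 1,
so the normaliser never vanishes), sexes never mix, and the final estimate
is `exp(fitted + smoothed residual) − floor`, clipped at a small positive
epsilon. Defaults ζ = 0.5, λ = 5 years, ω = 0.3 per year of age-midpoint
distance; a leave-one-year-out cross-validation utility
(`select_smoothing_loyo`) is provided for tuning but is not part of the
default pipeline. The exponential kernel forms and the default bandwidths
are this package's own choices; the framework only fixes that neighbours,
nearby years and nearby ages share information.

**Uncertainty.** 95% uncertainty intervals come from a Poisson parametric
bootstrap of the aggregated counts: each draw resamples every cell count as
Poisson(observed corrected count), reruns the entire two-stage estimator,
and the interval is the 2.5th–97.5th percentile band of the draws (widened,
if ever necessary, to bracket the point estimate from the unresampled
data). Coverage of true cell rates is verified by simulation in the
data-rich regime (hundreds of expected cases per cell), where the
log-Gaussian observation model is well calibrated; at extreme sparsity the
point estimator is conservative (geometric-mean-like) and nominal coverage
is not claimed. Aggregated intervals in the report tables (province ASR
extremes) take their width from the draws but are recentred on the point
estimate, because double resampling at sparse counts shifts the raw draw
distribution below the unresampled point.

## Cause split

Within each stratum the cause-group counts follow a Dirichlet-multinomial:
multinomial-logit mean with design year + age + sex + province (each term
optional), concentration φ > 0 capturing overdispersion, reference cause
"other" pinned at zero. Estimation is maximum a posteriori with a mean-zero
normal prior (sd 5) on every coefficient, by L-BFGS-B with an analytic
gradient (digamma terms); φ is estimated jointly on the log scale, bounded
in [e⁻⁵, e²⁰]. As φ → ∞ the likelihood converges to the plain multinomial
(checked numerically to relative 1e-3 at φ = 1e6). Province enters as a
prior-shrunk fixed-effect set rather than a second random-effects layer.
Predicted fractions (softmax) multiply the all-cause surface; summation
over causes restores it exactly. The default taxonomy is the six leading
childhood groups — leukemia, CNS, lymphoma, endocrine, digestive, urinary —
plus a residual "other"; any taxonomy with a marked reference can be
supplied as a two-column file.

## Derived measures

- **ASR**: direct standardisation, `Σ_a weight_a · rate_a`, default weights
  from the national age structure of the last study year (2016); supplied
  weights are normalised, so person-year totals work unchanged.
- **APC**: OLS of `ln(value)` on calendar year; reported as
  `100·(e^slope − 1)` %/year, the exponential-coefficient convention, which
  reproduces the published endpoint-based trend figures.
- **Decomposition**: the change in new cases between two years splits into
  population growth, population aging and rate change through two
  hypothetical datasets (baseline rates and structure scaled to the final
  total population; baseline rates applied to the final structure). The
  rate-change component is closed as `total − growth − aging`, so the
  telescoping identity holds to machine precision.
- **MIR**: year-wise mortality/incidence ratio, in crude or
  age-standardised mode (default age-standardised, the mode used for
  care-quality comparisons; lower is better).
- **Disparity**: provincial extremes reported as both absolute range and
  max/min ratio (the verbal "percent divergence" of such gaps is ambiguous,
  so both are emitted); ties break to the lowest province id.

## Synthetic registry

The generator is the study-conditions stand-in for a confidential registry:
31 provinces (packaged HASC codes, approximate census shares, first-order
adjacency), 1990–2016, a national under-15 population declining
log-linearly from 23.7M to 19.2M person-years, and a true rate surface

    rate = base · e^(slope·(t−t₀)) · age_mult · sex_mult · e^(u_p)

with base 6.5 per 100,000 (female, <1 year, 1990), slope 0.0065/yr, age
multipliers (1.0, 1.09, 1.36, 1.67), male:female ratio 1.3, and province
effects N(0, 0.25²) mixed one step along the adjacency graph with weight
ρ = 0.5 — the simplest mechanism yielding adjacency-structured correlation.
These defaults put the national ASR near 10 per 100,000 in 1990 with ~2,400
cases per year. Counts are Poisson given rate × person-years (the standard
registry model, which makes mean/variance checks analytic), thinned
binomially by the year's completeness. Near-duplicates are copies with
single-character or case/spacing name edits (so truth stays recoverable by
edit distance); missing fields are blanked independently per field. Cause
labels are drawn from year-drifting multinomial fractions whose defaults
emulate the observed shift toward leukemia and CNS tumours. Mortality is
Poisson around incidence mean × MIR(year), with a noise-free mode for exact
identities; the default MIR schedule declines log-linearly from 0.8 to 0.2
(end/start ratio 0.25).

**What the synthetic bed does not emulate**: real name corpora and
typography, migration, census microdata error, subtype-level (70-group)
taxonomies, non-Poisson clustering of registration, or province-varying
completeness. Passing tests therefore demonstrate that the machinery
recovers known structure under the stated noise model — not that the model
assumptions hold for any particular real registry.

## Problem sizes used in the test suite

Unit tests run on 2–6-province toy grids. The heavier properties use: 100
replicates of the stage-1 calibration on the full 31×27×4×2 grid; 20
replicates of the whole-pipeline province-ranking recovery at full default
scale (~30,000 records each); bootstrap coverage on a 6-province × 6-year
grid with 10 replicates × 60 draws; and 20 replicates each for the
multinomial coefficient and concentration recovery. The acceptance script
runs the worked-example quantities plus a 5-replicate ranking recovery.

## Known limitations

- The log-Gaussian stage 1 targets the geometric rather than arithmetic
  mean at low counts; national totals built from very sparse cells are
  mildly conservative (a Poisson-likelihood stage 1 would remove this at
  the cost of the linear residual definition).
- The hot-deck imputation ignores joint dependence beyond its conditioning
  set and will attenuate associations involving imputed fields.
- φ is weakly identified when most strata hold fewer than ~5 cases;
  estimates then lean on the prior and the coefficient shrinkage.
- Completeness correction assumes one national rate per year; differential
  under-registration by province biases subnational comparisons and cannot
  be detected internally.
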