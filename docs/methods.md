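# Methods

## Model and procedure

The pipeline estimates typical multi-year trajectories of an area-level
quality-indicator proportion in three steps.

### 1. Empirical-Bayes logit shrinkage

Each (area, period) cell carries an event count r (numerator procedures) and a
case count n (denominator hospitalizations). The area's continuity-corrected
logit `log((r+0.5)/(n−r+0.5))` is combined with the pooled logit of its parent
region through the precision weight `w = t²/(t²+s²)`, where
`s² = (n+1)(n+2)/(n(r+1)(n−r+1))` is the squared standard error of the
corrected logit and `t²` the between-area sample variance (denominator k−1) of
the k member logits in the region for that period. The shrunk logit is
`w·raw + (1−w)·pooled`; its inverse-logit is the stabilized proportion.

Choices the formulas leave open, and how this package resolves them:

- **Members entering t².** The member values m_j are the areas' raw corrected
  logits for that period and M their unweighted mean — the only quantities
  already defined per member.
- **All areas are shrunk**, not only sparse ones: w approaches 1 automatically
  for well-measured areas, so a hard "low event occurrence" cutoff would be
  redundant and would need an arbitrary threshold.
- **Pooled counts include the index area.** Leave-one-out pooling would make
  each area face a different regional target; the plain reading ("the
  prefecture's r and n") is simpler and symmetric.
- **Degenerate cases.** `t² = 0` (all members identical) gives w = 0 — every
  area takes the common pooled value, which then equals the common raw logit
  to within the continuity correction. A singleton region (k = 1) has no
  between-area variance; its area keeps its raw logit (w = 1). Cells with
  n = 0 have undefined s²; the default "region-fill" policy assigns the pooled
  regional value with w = 0 (the limit of the estimator as information
  vanishes), keeping the trajectory matrix rectangular. "drop-area" and
  "error" policies are available. All fallback rows are flagged in the output.
- Natural logarithm throughout.

### 2. Latent-class growth analysis

The N×T matrix of shrunk proportions is modeled as a K-component mixture of
regressions on a shared time basis: within class k,
`y_it ~ Normal(B(t)β_k, σ²)` with one σ² for all classes and periods (the
standard LCGA assumption — no within-class random effects). The EM algorithm
is run from a k-means initialization plus random posterior draws (default 10
starts, all seeded); the best final log-likelihood wins. Iterations stop when
|Δℓ| < 1e-8 or after 500 iterations. A start that leaves some class with all
posterior weights below 1/(10N) is discarded as collapsed; if every start
collapses, a convergence error reports the attempt. σ² is floored at 1e-12 so
noiseless (exactly separable) data remain finite; on such data posteriors
reach 0/1 and WMAE/WRSS vanish.

- **Response scale.** The model is fit to the shrunk *proportions* (bounded,
  the scale on which results are read); logit-scale fitting is a config
  option. Gaussian residuals on [0,1] are an approximation, adequate here
  because the shrunk values stay well inside the interval.
- **Basis.** Default cubic B-spline with df = 4 total columns — the smallest
  flexible basis that distinguishes "rising" from "flat" over 6–7 annual
  points. With df = 4 there are no interior knots (the basis spans cubics);
  larger df places interior knots at equally spaced quantiles of the period
  range. Linear and quadratic bases are available.
- **Model selection.** K is chosen over 1..5 as the argmin of
  `BIC = −2ℓ + p·log N` with N the number of areas and
  `p = K·d + (K−1) + 1`; ties resolve toward smaller K. WMAE
  (`Σ_ik p_ik Σ_t |y_it − μ_k(t)| / (N·T)`) and WRSS (same with squares, no
  normalization) are reported per K as complementary diagnostics but do not
  enter the decision — no principled combination rule exists, and BIC alone
  makes the choice reproducible.
- **Ordering and naming.** Groups are ranked by fitted mean at the final
  period (descending, stable under ties) and named
  `<band(first period)> to <band(last period)>` with bands low/middle/high cut
  at 0.45/0.60 on the proportion scale (config values; duplicates get numeric
  suffixes). The cutoffs were set so the default world's four groups map to
  the canonical HH/MM/LM/LL labels; real analyses should set them from the
  indicator's clinical context.

### 3. Group profiling

Covariate profiles use modal (hard) assignment and report per-group medians
and quartiles with linear interpolation between order statistics (the "type 7"
quantile convention, the numpy default — stated so quartiles are exactly
reproducible). Areas missing a covariate are excluded for that covariate only,
with the exclusion count logged. Survey-year trend tables report per-group
medians for each year and their difference. No between-group hypothesis tests
are computed — the analysis is descriptive.

## The synthetic world

The generator stands in for an access-restricted national claims database. It
draws, per area: a parent region (335 areas across 47 regions, each region
non-empty), a latent trajectory group (shares 62/20/5/13%), an area-level
logit intercept `a_i ~ Normal(0, 0.05)`, and a population
`~ LogNormal(log 250000, 0.2)`. Per period, case counts are
`n_it ~ Poisson(population × 60/100000)` (≈ 150 AMI cases per area-year, the
order of magnitude implied by ~470k national cases over 6–7 years across 335
areas) and events `r_it ~ Binomial(n_it, expit(curve_g(t) + a_i))`. Default
group curves: flat at logits 1.0 (HH), 0.2 (MM), −0.62 (LL), and a rising
group from −0.45 to 0.2 (LM) — three flat levels separated by ≥ 0.8 logit
units plus one catching-up group, mirroring the qualitative pattern the method
is meant to detect. Covariates are drawn log-normal (population, density,
income) or normal truncated at zero (per-100k staffing and facilities), with
multiplicative group shifts giving higher-trajectory groups denser healthcare
supply; four covariates get correlated 2014/2018 survey-year variants.

**What the generator does not emulate — and what green tests therefore do not
establish.** Two simplifications matter:

- *Population spread.* Real sub-prefectural populations span more than an
  order of magnitude (log-SD ≈ 0.8–1), making binomial noise strongly
  heteroskedastic across areas. The default uses log-SD 0.2. Under the
  realistic spread, the shared-σ² mixture is misspecified and the BIC argmin
  overshoots the true K essentially always (measured: K = 5 chosen even with
  area heterogeneity as low as SD 0.02 on the logit scale; residual SD 0.063
  in the smallest-denominator quartile vs 0.023 in the largest).
- *Area-level heterogeneity.* Persistent area intercepts beyond SD ≈ 0.1 logit
  make the maximum-likelihood K = 4 solution split the largest flat group
  rather than isolate the small rising group (ARI drops to ≈ 0.5–0.9 at
  SD 0.15).

Both are intrinsic properties of LCGA with iid Gaussian residuals, not
implementation artifacts; they are the likely reason real-data analyses of
this design select K by judgment "based on BIC *and* WMAE" rather than by a
strict argmin. The default world is deliberately an interior design point
where the estimator's stated recovery properties (ARI ≥ 0.9, BIC argmin at
the true K) hold, so that the tests verify the machinery; they do not certify
BIC consistency on real claims panels. The failing regimes are reproducible by
raising `area_random_sd` and `population_log_sd` in `SimulationConfig`.

Other stated-world choices: 7 fiscal years starting 2014 (the study window is
reported inconsistently as 6 or 7 years; 7 is the default, configurable);
Poisson case counts on population (the real case-count distribution is
unobserved; Poisson is the minimal assumption and is flagged as such);
covariate distributions are qualitative stand-ins matching sign and skew, not
calibrated to census tables.

## Numerical choices

- EM tolerance 1e-8 on |Δℓ|; max 500 iterations; empty-class floor 1/(10N);
  σ² floor 1e-12; posteriors computed in log space via logsumexp.
- The weight is computed as t²/(t²+s²), never via 1/t², so t² = 0 is exact.
- Modal labels break posterior ties toward the lowest class index.
- All randomness flows from explicit seeds; the pipeline expands one root seed
  per stage via `numpy.random.SeedSequence`, and k-means receives a derived
  integer seed. Reruns are bit-identical.
- Vectorized shrinkage reproduces the scalar formula composition to 1e-12
  (tested on 200 random panels including zero-case cells and singleton
  regions).

## Known limitations

- No class-specific residual variances, no within-class random effects, no
  covariates in the membership model (growth-mixture extensions are out of
  scope by design).
- Gaussian likelihood on proportions ignores the known binomial sampling
  variance of each cell; a weighted or beta-likelihood variant would use the
  denominators directly.
- BIC model selection is anti-conservative under heteroskedastic noise and
  residual area heterogeneity (see above); treat the chosen K as a lower-bound
  summary of structure, and inspect WMAE and the fitted curves.
- The shrinkage target is the parent region only; national or
  covariate-adjusted priors are not implemented.
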