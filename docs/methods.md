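# Methods

`mbcwarm` asks whether soil microbial biomass carbon (MBC) declines under
warming, using three statistically independent routes, and provides a
synthetic world with known ground truth so each route can be validated by
parameter recovery rather than by eyeballing.

## 1. Effect sizes and random-effects pooling

Each field warming experiment contributes a paired observation
(MBC under warming, MBC under control). The effect metric is the log
response ratio

    LN(RR) = ln(MBC_t) − ln(MBC_c),

whose delta-method sampling variance, when per-arm SDs and replicate counts
are reported, is

    v = s_t² / (n_t · m_t²) + s_c² / (n_c · m_c²).

Pooling uses the DerSimonian–Laird (DL) moment estimator: with fixed-effect
weights w_i = 1/v_i and Q = Σ w_i (y_i − ŷ_F)²,

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),

then random-effects weights w* = 1/(v_i + τ²), pooled mean μ = Σw*y/Σw*,
SE(μ) = (Σw*)^(−1/2), normal-quantile 95% CI, and I² = max(0, (Q−(k−1))/Q).
A warming effect counts as a "significant decrease" only when the entire CI
is below 0.

**Missing dispersion.** Field compilations rarely report dispersion for
every study. When some studies report SDs, missing sampling variances are
imputed with the mean reported variance; when none do, pooling falls back
to an unweighted method-of-moments fit (μ = mean, τ² = sample variance).
The method actually used is recorded on the result (`method` field).

**Bins.** Warming-magnitude groups are <1, 1–2, 2–3, 3–4 and 4–5 °C;
duration groups are <3, 3–6 and 6–30 years. Intervals are
left-closed/right-open, with the last bin closed, so every record lands in
exactly one bin. Bins with a single study are reported as unpoolable, never
silently dropped.

**Dose–response.** A quadratic OLS fit of LN(RR) on warming magnitude
(ΔT, ΔT²) reports coefficients, adjusted R² and the overall-F p-value.

## 2. Publication bias

The Egger test regresses the standardized effect y/s on precision 1/s; the
intercept's two-sided t-test flags funnel asymmetry at p < 0.05. The test
presumes the spread of effects is dominated by sampling error: under strong
between-study heterogeneity its size inflates (hence the calibration world
in the tests is homogeneous) and its power against selection falls.

Trim-and-fill is the iterative Duval–Tweedie procedure: re-center on the
current pooled mean, estimate the number of suppressed studies with the L0
rank-sum estimator (R0, the rightmost-run estimator, is a config switch),
trim that many of the most extreme studies on the overrepresented tail,
re-pool, iterate to convergence, then mirror the trimmed studies about the
final center and re-pool on the filled set with the same DL machinery.
`side="auto"` picks the trimmed tail from the sign of the Egger intercept
(positive intercept → studies missing on the left → trim the right); plain
rank-sum comparison is used only when Egger is unavailable (identical SEs),
because under one-sided suppression the truncated set is skewed and the
below-center count otherwise drags the rank sum to the wrong tail.

Known limitation: when suppression is probabilistic and effect-based (every
study below a cutoff dropped with some probability) rather than
rank-based removal of the most extreme studies, both L0 and R0
underestimate the number missing — a documented weakness of trim-and-fill,
not of this implementation. The validation scenarios therefore follow the
estimator's own missingness model (extreme-tail removal).

## 3. Long-term site regressions

Each multi-year in-situ series gets a simple OLS fit of MBC on annual mean
temperature. CIs use the t-distribution with n−2 degrees of freedom —
series run from 3 to ~10 points, where normal intervals would be
anti-conservative. A site shows "no significant correlation" when its CI
spans 0; on null worlds (zero temporal sensitivity) about 5% of site fits
are expected to be falsely significant, which the tests verify.

## 4. Space-for-time (SFT) diagnostic

A Random Forest trained on *spatial* MBC observations is asked a *temporal*
question: predict annual global MBC for 1992–2013 on a grid whose only
time-varying field is temperature (linear +0.28 °C over the period). The
diagnostic repeats, for each of 200 bootstrap replicates of m = 500 rows
drawn with replacement from the n = 762 observations:

1. univariate OLS slope of MBC on temperature (the spatial gradient);
2. Random-Forest fit (default 500 trees, ⅓ of features per split,
   unlimited depth; land cover one-hot encoded against a fixed global class
   list so subsamples missing a class stay alignable; single-threaded and
   seeded, so runs are bit-reproducible);
3. an area-of-applicability mask: either the χ²(0.975)-quantile
   Mahalanobis ellipsoid of the training predictor cloud, or a
   dissimilarity index (nearest-training-point distance in standardized,
   importance-weighted predictor space over the mean pairwise training
   distance, thresholded at the upper whisker of the training leave-one-out
   DI). Both thresholds are config switches; a shared-mask mode intersects
   all replicate masks instead;
4. predicted global totals per year (area-weighted, masked cells excluded
   from every year equally) and the change rate: OLS trend of total vs
   year, normalized by the period-mean total (initial-year denominator is a
   switch), ×100 → % yr⁻¹. The per-replicate rate CI comes from the
   year-trend SE.

The summary reports the across-replicate mean change rate with a
mean ± 1.96·SD/√reps CI and the Pearson correlation between per-replicate
change rate and spatial slope. A negative mean rate with zero true temporal
sensitivity, together with a positive rate–slope correlation, is the SFT
artifact: the model converts the spatial gradient into a phantom temporal
trend.

## 5. The synthetic world

**Warming pairs** (default 130, the scale of real compilations): control
MBC is log-normal (median 60 mmol kg⁻¹); the true LN(RR) is the bin effect
plus N(0, 0.15²) between-study noise; default bin effects are a small
increase at 1–2 °C (+0.08), a decrease only at 4–5 °C (−0.15) and zero
elsewhere — the pattern the field evidence shows. Reported arm means carry
replicate-level sampling error; per-study relative SD is log-normal around
0.20 (spread 0.5 on the log scale) because a funnel plot is degenerate if
every study has the same precision. Publication bias is injected by
dropping, with probability `suppress_prob`, studies whose observed LN(RR)
falls on one side of a cutoff.

**Long-term series**: per site, MBC = baseline + sensitivity × (T − T̄) +
N(0, noise); temperatures fluctuate (SD 0.7 °C) around a site mean; series
lengths 3–10 years, six sites by default.

**Spatial world**: an abstract lattice (no geography) of cells carrying
nine continuous predictors plus categorical land cover. The latent
correlation structure is block-diagonal: temperature is collinear with pH,
texture and elevation, while the predictors that *drive* MBC (SOC,
precipitation, nitrogen, NDVI — and the land-cover assignment) are sampled
independent of temperature and their MBC contributions are built from
latents residualized against the temperature latent. This makes the
configured spatial slope the *entire* MBC–temperature dependence across
space — marginal and conditional alike — so it can honestly be dialed to
zero: without this, the forest finds a residual partial temperature
dependence and the artifact never fully vanishes in the control world.
Baseline MBC is 200 mmol kg⁻¹ at the mean-temperature cell with slope −8
mmol kg⁻¹ °C⁻¹ by default and additive N(0, 15) noise, floored at 0.5
(generating on the log scale instead would make the configured linear slope
unrecoverable; the floor is vanishingly rare at these settings). The 22
annual temperature layers warm linearly by exactly +0.28 °C; true cell
trajectories respond to warming only through `temporal_sensitivity_true`
(zero by default — the artifact regime).

What a green test does *not* establish: the synthetic world has no spatial
autocorrelation, no coastlines or real rasters, equal cell areas, a single
time-varying predictor, and observation locations sampled uniformly — so
magnitudes (e.g. a −0.04 % yr⁻¹ artifact at slope −8 and mean MBC 200) are
not comparable to published global rates; only directions, calibrations and
recovery properties are.

## 6. Numerical choices

- Normal 97.5% quantile 1.959963984540054 for meta-analytic CIs (matching
  the convention of standard meta-analysis tooling); t-quantiles for
  per-site slopes and n−2 df.
- DL τ² truncated at 0; I² truncated to [0, 100].
- Trim-and-fill iterates to k0 convergence with a 50-iteration guard;
  k0 is capped at k−2 so the trimmed set stays poolable.
- Mahalanobis masks ridge-regularize an ill-conditioned training
  covariance (escalating ε, hard failure if still singular).
- Bootstrap replicate seeds are spawned from a master `SeedSequence`;
  scikit-learn forests run single-threaded with explicit seeds.
- Replicate failures (degenerate subsample) are excluded and counted,
  never silently imputed.

## 7. Known limitations

- Trim-and-fill under effect-based probabilistic suppression underestimates
  k0 (see §2); the Egger test loses power under strong heterogeneity.
- The across-replicate CI of the mean change rate reflects bootstrap
  variability only; world-level (sampling-of-nature) variability requires
  generating multiple worlds, which is how the flat-slope control is
  evaluated in the tests.
- Random-Forest predictions are not exactly invariant to rescaling the
  response (near-tied splits resolve differently in floating point), so
  unit invariance of the change rate holds exactly for the rate computation
  and only approximately through a refitted forest.
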