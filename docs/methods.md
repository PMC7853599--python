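# Methods

## The growth model and its decomposition

Canopy height of winter wheat rises roughly linearly through stem
elongation (SE) and plateaus at the final height (FH). Between consecutive
observations the stem elongation rate is `SER = ΔCH/Δt` in mm d⁻¹.
Below about 25 °C — the regime covered by spring field conditions in the
temperate zone — elongation responds approximately linearly to ambient
temperature, so each plot is summarized by an ordinary least-squares fit

    SER = a·T + b_Tcrit + ε,

with `T` the mean daily air temperature of the measurement interval. The
slope `a` measures temperature responsiveness (mm °C⁻¹ d⁻¹). An intercept
is only interpretable at a stated temperature: at 0 °C it is strongly
negatively correlated with the slope across plots, at 20 °C strongly
positively. Because the correlation between slope and the intercept
evaluated at `T*`,

    r(T*) = [cov(a, b₀) + T*·var(a)] / [sd(a)·sd(b₀ + T*·a)],

has a numerator linear in `T*`, it crosses zero exactly once, at
`T_crit = −cov(a, b₀)/var(a)`. The package locates `T_crit` the way the
field procedure does — scanning 1 °C to 22 °C in 0.01 °C steps and taking
the grid point with minimal `|r|` (ties toward lower temperature, edge
minima flagged out-of-range) — and uses the closed form only as an
independent test oracle. The intercept at `T_crit` ("vigour") is
uncorrelated with the slope and serves as the temperature-irresponsive
growth component. `T_crit` is computed per year; the cross-year trait
values are the genotype BLUEs of the per-year values.

Intervals entering the regression are "interior" growth intervals: an
interval is used only when it and both neighbours show SER above a floor
(default 2 mm d⁻¹). Boundary intervals mix growing and non-growing days
and are not linear in temperature, and plateau intervals carry pure
measurement noise; the floor sits several noise standard deviations above
zero but far below active growth. With the floor at 0 and noiseless data
the rule reduces to exact interior selection, which is what makes the
machine-precision conservation test possible.

## Phenology extraction

- **FH** is the terminal plateau: the first observation after which no
  increase reaches `tol` (default 5 mm) any more, confirmed by at least
  `k_flat` (default 3) consecutive sub-tolerance increases. FH is the
  maximum height up to and including the confirming run, which keeps late
  noise out while still containing the first capped observation. Series
  may be flat *before* growth starts, so the search anchors on the last
  real increase rather than the first flat run. Without a terminal plateau
  FH falls back to the overall maximum and the plot is flagged
  (`no_plateau`) rather than dropped.
- **GDD_15 / GDD_95**: normalized height (100·CH/FH) is linearly
  interpolated to calendar days, and the first upward crossings of 15% and
  95% are mapped onto cumulative growing degree-days
  (Σ max(T−T_base, 0) from sowing; base 0 °C, the wheat convention —
  configurable). Crossing positions are sub-day interpolated. Noise-induced
  re-crossings are ignored (first crossing rule). A plot already above 15%
  at the first observation is flagged `start_missed`; one that never
  reaches 95% is flagged `phase_incomplete`; both yield NaN timings and are
  excluded from the affected trait, never imputed.
- **Durations**: GDD_SE = GDD_95 − GDD_15 exactly; time_SE inverts the
  thermal-time map by linear interpolation to express the same span in
  calendar days.
- Interval mean temperature uses the half-open interval (start, end], so
  each day's growth is attributed to exactly one interval; the same
  convention drives the simulator, which is why noiseless recovery is
  exact rather than approximate.

## Spatial correction

Per measurement date, plot values are decomposed as

    y = genotype + f(row, range) + row + range + ε,

with `f` a tensor-product cubic P-spline (second-order difference
penalties; basis size per axis = ceil(2/3 · axis length), following
standard practice for augmented wheat grids) and ridge-penalized row and
range effects. Genotype effects are unpenalized (fixed); the smooth and
the row/range predictions are column-centered so the grand mean stays with
the genotype component and is preserved exactly. The two smoothing
parameters (surface, ridge) are selected by generalized cross-validation
on log-spaced grids; within a year they are selected on the first
qualifying date and reused, since the field geometry does not change
within a season. "Corrected plot value" = estimated genotype effect +
residual, so genotype contrasts and replicate-level noise pass through
while trend, row and range components are removed. This is a deliberately
self-contained re-implementation in the PS-ANOVA spirit, not a numerical
clone of any particular spatial-analysis package; its contract is
trend-recovery behaviour (an injected smooth bowl must decorrelate from
the corrected residuals), near-identity on trend-free data, approximate
idempotence, and mean preservation — all property-tested.

Dates observed on fewer plots than genotypes, or on less than 90% of
plots (configurable), are skipped with a logged warning and NaN corrected
values.

## Genotype × year analysis

Spatially corrected plot values feed the crossed model
`y_pij = μ + G_i + Y_j + GY_ij + ε_pij` with fixed years, random GY, and
genotype either fixed (adjusted means/BLUEs) or random (BLUPs, variance
components). Only genotypes present in all years enter; the rest are
reported as dropped. REML is implemented directly: the restricted
likelihood factorizes into within-cell replicate contrasts (depending only
on σ²_ε) and genotype-year cell means with variance σ²_GY + σ²_ε/r (plus a
genotype block σ²_G when G is random), so each evaluation is a small
weighted least-squares problem — the genotype-fixed case absorbs the
genotype dummies by Frisch–Waugh demeaning. The optimizer (Nelder–Mead on
log variances) is started at the expected-mean-squares ANOVA estimators,
which on balanced data with interior estimates *are* the REML optimum;
the better of start and polish by restricted likelihood is kept, and
boundary estimates are truncated to zero. Balanced-data agreement with the
classical ANOVA estimators is asserted at 1e-6 relative in tests.

Heritability on a genotype-mean basis:

    H² = σ²_G / (σ²_G + σ²_GY/n_years + σ²_ε/(n_years·n_reps)),

i.e. divisors 3 and 6 for three years × two replicates. Traits scored once
per environment (heading) omit the GY term and divide the residual by the
number of year-site replications. Reported heritabilities are rounded to
two decimals.

The final-height model regresses FH BLUEs on slope, vigour, GDD_SE and
0/1-coded *Rht-B1*, *Rht-D1*, *Ppd-D1* contrasts (wild type = 0) with all
two-way interactions. Collinear columns — typically an allele-by-allele
interaction no genotype carries — are detected by a scaled greedy rank
check (main effects enter first, so only the later term of a collinear
pair is dropped) and reported by name; the reduced model gets a type II
ANOVA. Cross-year accuracy is the squared Pearson correlation between a
model trained on one year's BLUEs and another year's observed BLUEs.
Correlation matrices use pairwise-complete Pearson coefficients with
two-sided t-based p-values and no multiplicity adjustment; the
multiple-testing rule for association scans is the Bonferroni threshold
`−log10(α/n_tests)`.

## The synthetic trial generator

The generator inverts the analysis model: inside a genotype's SE window
(thermal time `start_gdd` to `end_gdd` after sowing) the latent daily
height increment is `max(vigour + slope·(T_d − T_crit), 0)` mm, zero
outside; heights integrate from a baseline and cap at FH. Using the true
`T_crit` (12 °C) as the rate's reference temperature makes slope and
vigour independent by construction. FH is *derived* from the integrated
window growth (window growth = 85% of FH, baseline = 10%), so the 15% and
95% crossings align with the window bounds and the positive slope–FH
correlation seen in real canopies emerges mechanistically rather than by
decree. Negative latent growth is clamped at zero; observation noise can
still produce negative observed SER, as raw field data do.

Scenario defaults are the study conditions: 330 genotypes × 2 replicates ×
3 years on a 41 × 47 grid with diagonally offset replicate blocks
(gap 5 — replicate 2 occupies ranges 27–47, matching the published
geometry); sowing mid-October; daily temperature = seasonal sinusoid
(annual mean 9.5 °C, amplitude 8.5 °C) + AR(1) deviations (ρ = 0.75,
sd 2.8 °C, the synoptic variability that makes the slope identifiable
within a season); twice-weekly observations (alternating 3/4-day gaps)
over 74 days from mid-April, i.e. 22 per season, within the 17–22 range of
a real campaign. Genotype parameters: slope ~ N(1.2, 0.27²) mm °C⁻¹ d⁻¹,
vigour ~ N(12, 0.84²) mm d⁻¹, SE onset ~ N(870, 35²) °C·d, window length
~ N(700, 24²) °C·d; the genotypic standard deviations put simulated
variance components on the scale reported for European winter wheat
panels. Allele frequencies follow the panel (7% *Rht-B1b*, 58% *Rht-D1b*,
13% *Ppd-D1a*); dwarfing alleles act through a vigour multiplier
(0.90/0.93) and an additive, rate-invisible height shift (−8/−6 cm,
shorter vegetative canopy); *Ppd-D1a* shortens the window by 40 °C·d.

Two calibrated magnitudes deserve explicit justification:

- **Measurement noise, 3 mm s.d.** The plot-level precision of
  LIDAR-derived canopy height is not published; 3 mm (sub-centimeter) is
  realistic for terrestrial laser scanning of micro-plots and, propagated
  through the interval regression, puts the residual variances of slope
  and vigour on the order of the published ones. Configurable.
- **Genotype-by-year variance, 0.4 × genotypic (one dial for all
  parameters).** Because the correlation between true genotype values and
  their cross-year BLUEs is √H² under this design, a recovery criterion of
  r > 0.9 mathematically requires H² > 0.81; the ratio 0.4 lands simulated
  slope heritability at ≈ 0.82 (near the published 0.81) while giving the
  recovery check a workable margin. Real data show trait-specific ratios —
  notably GY > G for SE duration — which a single dial does not reproduce.

## What passing tests do and do not show

The simulator shares the analysis model's functional form, so end-to-end
recovery demonstrates the pipeline's statistical machinery — interval
selection, decorrelation scan, spatial adjustment, REML — not the
biological adequacy of a linear temperature response. Real canopies add
lodging, senescence of flag leaves, scan artefacts, nonlinearity above
25 °C and trait-specific G×Y structure, none of which are emulated; no
light, water, vernalization or photoperiod mechanism is modelled, and the
point-cloud-to-height step is upstream of this package. Because simulated
FH is a near-deterministic integral of the growth law, allele effects
routed through the trajectory are almost entirely absorbed by the growth
traits in the final-height model; the cohort-level test therefore asserts
the realistic qualitative pattern (growth-trait sums of squares orders of
magnitude above allele terms, strong unadjusted dwarf contrast) rather
than stand-alone allele significance. Mapping crossings onto the daily
thermal grid leaves a ~2% genotype-by-year trace on the timing traits even
in noiseless runs, which is why their noiseless heritabilities are ≥ 0.98
rather than exactly 1.

## Numerical choices and degenerate inputs

- T_crit scan: nearest grid point, no sub-grid interpolation; plots whose
  regression fails preconditions (fewer than 3 growth intervals, zero
  temperature variance) are excluded and reported, never imputed.
- REML: variances optimized on the log scale with a floor of 1e-10 × the
  data variance; estimates at the floor report as exactly zero. Degenerate
  all-zero-variance data raise rather than return 0/0.
- Spline fitting adds a 1e-8-scaled ridge to the penalized blocks so the
  constant direction (confounded with the genotype intercept) and the
  penalty null space stay identifiable.
- Rank detection for singular model terms operates on norm-scaled columns
  with an SVD tolerance, so allele indicators with few carriers are not
  spuriously dropped next to large-scale thermal-time columns.
- Determinism: every stochastic step flows from one seeded generator;
  seeded runs are byte-identical including the JSON run report.

## Problem sizes used in tests

The full-cohort checks run the default scenario (330 genotypes, 1 980
plots, ~40 000 observations) once per session; the variance-component
simulation study uses 300 genotypes × 3 years × 2 replicates over 20
seeds; spatial property tests use 150 genotypes on a 25 × 30 grid and an
80-genotype three-year trial for the time-series correction. These sizes
keep the whole suite under a minute while matching the study's scale where
it matters (the cohort-level recovery checks).
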