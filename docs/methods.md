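# Methods

This note documents the models implemented in `stemflux`, their
assumptions, the defaults and why, and what the synthetic-data generators
do and do not emulate.

## Chamber flux computation

A closed chamber of volume V (cm³, chamber plus tubing) clamped over a
collar of area S (cm²) accumulates CO₂; the efflux per unit stem surface is

E_A = 10 · V · P₀ · (1 − W₀/1000) / (R · S · (T₀ + 273.15)) · ∂C′/∂t  [µmol m⁻² s⁻¹]

The slope ∂C′/∂t is ordinary least squares on the samples with
t ≥ dead band (default 90 s of a 180-s closure), because the headspace is
not mixed immediately after closure. "Initial" conditions P₀, W₀, T₀ are
taken from the first post-dead-band sample, the first instant the fit
trusts. Two modes: `closed_system` includes the water-vapour dilution term
(1 − W₀/1000); `ideal_gas` forces W₀ = 0, matching analysers that report a
dry mole fraction. The two coincide exactly for dry air (tested).

Numerical conventions:

* a zero-variance (flat) series returns slope 0 with r² **defined as 0**,
  so the minimum-r² QC gate still applies to it;
* fewer than 3 post-dead-band points raises `DegenerateSeriesError`;
* unit conversion to mg C m⁻² h⁻¹ multiplies by 12.011 × 3600 / 1000 =
  43.2396 (molar mass of carbon 12.011 g mol⁻¹);
* Q₁₀ standardization is E_A · Q₁₀^((T_ref − T)/10), default Q₁₀ = 2.0 to
  25 °C. It is **off by default for diel series** (their variation is the
  signal of interest) and opt-in for vertical profiles.

Quality control: fits with r² below a configurable gate (default 0.9) are
flagged `leak` — leaks and mechanical faults destroy linearity, and no
sharper numeric criterion is defensible from first principles. Negative
fluxes are flagged `error`. Remaining values pass a per-tree outlier rule:
drop anything beyond 1.5 interquartile ranges outside the quartiles, with
quartiles by linear interpolation between order statistics
(`numpy.percentile` default). Groups under 4 values pass through with a
warning. The rule is deliberately **single-pass**: re-applying it to its
own output contracts the fences and can remove further points, so it is
not idempotent and is never iterated.

## Surface area

Four estimators per tree, all in m²:

* **SA_a** — the Chambers diameter polynomial,
  SA = 10^(−0.105 − 0.686X + 2.208X² − 0.627X³), X = log₁₀(DBH cm). Note
  a real limitation: the cubic's derivative changes sign at X ≈ 2.182, so
  SA *declines* for DBH beyond ~152 cm. That is extrapolation behaviour of
  the fitted polynomial, not biology; monotonicity is only guaranteed (and
  tested) up to 150 cm.
* **SA_ha** — SA_a times a height-correction coefficient: the mean over
  census trees of reference-model predicted height divided by site-model
  predicted height at the same DBH. The averaging set is all census trees
  (a DBH grid would weight sizes arbitrarily). The site model is
  height = 14.779 · ln(DBH) − 24.546; natural log is the only base under
  which these coefficients give a plausible 27–65 m canopy, and the log
  base is an explicit field of `HeightModel` so it can never be confused
  with the allometry's log₁₀. The default coefficient 1.669 comes from
  literature reference allometries outside this package and is consumed as
  configuration; any object with `predict(dbh)` can be injected as the
  reference (e.g. an East-Central Amazonia equation), and
  `ScaledHeightModel` covers the constant-ratio case.
* **TLS_t0 / TLS_t2** — sums of **lateral** cylinder area 2πrL over a QSM
  (no end caps: adjacent cylinders abut). The 2-cm truncation applies per
  cylinder by its own diameter — the only rule well-defined on a bare
  cylinder table — with ≥ 2 cm kept.

Plot totals carry Monte Carlo SEs: each tree's SA is drawn from
Normal(sa, sd) with sd the spread across QSM refits, 10 000 draws by
default, trees independent; the SE is the SD of the plot sums. Negative
draws (possible under large sd) are clipped to zero and counted; the SE
converges to √(Σ sd²) (tested at 10⁵ draws within 2%). The conventional
10% SE on allometric totals applies to the **plot total** by default
(configurable per tree), since it describes the allometry, not individual
stems.

## Vertical model

E_A ~ intercept + b·log(height) + buttress + above_branch + (1 | tree),
fit by REML (`statsmodels.MixedLM`); REML because the variance components
matter for inference with 13 trees. The stem class is the reference;
effects are additive offsets. Position classes absent from the data are
reported as `None` — absent, not zero — and a height covariate without
variation leaves the slope `None` (unidentifiable) rather than zero.
Confidence intervals use t critical values with df = n_trees − 1: the
random intercept makes between-tree information the binding sample size,
and Wald-z undercovers with 13 groups.

Cylinder classification (`PositionRules`): the trunk is followed from the
root, continuing through the largest-radius child; the **first major
branching point** is the lowest base height where a non-continuation child
has radius ≥ 0.5 × its parent's (the ratio is configurable; no sharper
definition is available from field practice). Cylinders based at or above
that height are `above_branch`; trunk cylinders below 3 m (default
buttress top) on buttressed trees are `buttress`; the rest are `stem`.
Every cylinder gets exactly one class, deterministically.

Prediction is population-level (random intercept 0) at the cylinder
midpoint height, floored at 0.1 m so log() stays finite at the tree base
(the floor is exposed in `PositionRules`); negative predictions are
floored at zero. Predictions for a class whose effect was never estimated
raise rather than silently assume zero.

## Diel analysis

Each tree's E_A series is z-scored (sample SD) to remove level and scale
differences between trees; the diel question is about *shape*. The
normalized series is regressed per tree on a K = 2 harmonic basis
{sin, cos}(2πk·hour/24), k = 1..2, by least squares, with no intercept:
the data are zero-mean and the basis integrates to zero over a cycle, so
predictions are daily departures and are exactly periodic at the 0/24
boundary. This harmonic regression is a deliberate, fully specifiable
approximation of penalized cyclic-spline smoothing — same inferential
target (a smooth periodic hour effect per tree), no smoothing-parameter
machinery. K = 2 resolves one broad afternoon feature plus asymmetry;
rank-deficient designs (too few observations for the requested harmonics)
raise.

Each integer hour is then tested across trees: a one-sample Wilcoxon
signed-rank test of the per-tree predicted departure against zero. Testing
one prediction per tree per hour — not raw observations — sidesteps
within-series autocorrelation at the cost of power. Fewer than 5 trees
triggers an underpowered warning; an all-zero hour is reported p = 1. No
multiple-testing correction is applied across the 24 hours by default
(each hour is a separate practical question: "is a reading at this hour
biased?"); a Holm option exists. The recommended measurement window is the
non-significant hours merged into contiguous wrap-around intervals.

Note that with zero-mean normalization, a genuine depression in one part
of the day *necessarily* elevates the rest relative to the daily mean; in
cohorts where only the depression is shared and the rest of the cycle is
heterogeneous across trees, only the depression hours flag consistently.

## Stand upscaling

Uniform mode: stand E_A = mean rate × Σ SA × 24/10⁶ (mg h⁻¹ → kg C d⁻¹),
SE from the rate SE and plot-SA SE in quadrature (first order). Vertical
mode: Σ over cylinders of predicted rate × lateral area, honouring the
method's truncation; its SE propagates only surface-area uncertainty
(each tree's QSM sd scaled by its area-weighted mean rate), because method
differences, not fixed-effect noise, are the signal of interest. Both
modes are linear and additive over tree partitions, and a flat vertical
model (zero slope, zero offsets) makes them identical to floating
precision — the mechanism by which vertical E_A variation leaves stand
totals unchanged whenever surface area is estimated correctly.

Pairwise method comparison uses normal-approximation z-tests on propagated
SEs (|z| > 1.96 flagged) — a simplification of mixed-model contrast
machinery with the same decision semantics on these totals. Annualization
(× 365/1000 per ha) is a labelled convenience, never applied silently.

## Synthetic data

Generators are pure functions of config + seed and define the simulated
study conditions:

* **Census**: 397 stems, DBH from a truncated power-law (exponent 2.2,
  range 10–210 cm, giving P(DBH > 50) ≈ 0.12 — the plot's size
  structure); heights = site model + N(0, 4 m), floored at 5 m; 66/397
  buttressed.
* **QSMs** (190 trees, largest first): a geometrically tapered 1-m-segment
  bole from DBH and height, basal flare on buttressed trees, one major
  branch at 55–80% of height, and six sub-2-cm "twig bundle" cylinders.
  Branch and twig areas are calibrated so each tree's total tracks
  1.669 × the diameter-only allometry (lognormal scatter, σ = 0.1) with
  35–45% of area below 2 cm — the observed TLS area structure at a
  tall-statured site, where the diameter-only allometry undershoots and
  2-cm truncation strips a large share. Cylinder counts are far below a
  real QSM's; areas, not topology, are the emulated quantity. Per-tree
  `sa_sd` is 5% of SA, standing in for the spread across QSM refits.
* **Chamber series**: CO₂(t) = C₀ + slope·t + N(0, 0.5 µmol mol⁻¹) at
  1 Hz, where the slope is the exact algebraic inversion of the flux
  equation — so the noiseless round trip is an identity and the noisy
  recovery error has a closed-form OLS SE (`analytic_slope_se`).
* **Vertical observations**: 13 trees × 4–7 heights ~5 or ~10 m apart;
  the lowest observation on buttressed trees sits on the buttress and
  every second tree's top observation is above the branch point, so all
  three classes are represented at the campaign's design size. Truth:
  intercept 95.77, slope 0, buttress +40, above-branch +30 mg C m⁻² h⁻¹,
  tree SD 10, residual SD 5.
* **Diel observations**: 18 trees, hourly over 48 h in 2 continuous runs
  of 11–22 h (battery-limited logging), baseline lognormal around
  59.30 mg C m⁻² h⁻¹, per-tree amplitude 5–35% and uniform random phase
  (mixed afternoon peaks and dips), residual noise 12% of baseline.
  `DielPatternSpec.null()` removes all signal;
  `DielPatternSpec.common_depression()` multiplies all trees by a smooth
  bump centred in 15:00–19:00 (depth 50%).

What the generators do **not** emulate: real QSM topology and cylinder
counts, species-specific allometries and traits, temperature/VPD-driven
flux dynamics (the diel cycle is imposed, not mechanistically generated),
instrument drift, and spatial structure within the plot. Passing tests
therefore demonstrate that the estimators recover known structure of the
right scale and design — not that field data meet the models' assumptions.

## Problem sizes and tolerances in the validation suite

Flux round-trip coverage uses 1000 series against a 3σ analytic OLS bound
(expected coverage 99.7%, asserted ≥ 95%). The flux equation is checked
against an independent SI-unit evaluation to 6 significant figures on a
100-point grid. Vertical-model CI coverage uses 200 replicates at the
13-tree design (asserted ≥ 90% per fixed effect). Diel type-I control
uses 1000 null cohorts (asserted ≤ 7% of hours flagged at α = 0.05);
depression recovery uses 100 cohorts (asserted ≥ 90% with all five
injected hours flagged and excluded from the window). Monte Carlo SEs are
checked at the standard 10 000 draws (5%) and at 10⁵ draws (2%). These
sizes keep the full suite under a minute while leaving Monte Carlo error
well inside every asserted margin.

## Known limitations

* The Chambers polynomial turns over beyond ~152 cm DBH (above).
* Branch E_A below 2 cm diameter is outside scope: the vertical model has
  no data there, and truncated methods exclude that area entirely.
* The harmonic diel model cannot represent features sharper than its
  highest harmonic; localized events shorter than ~6 h are smeared.
* Vertical-mode stand SEs omit fixed-effect prediction uncertainty by
  design; enable it only if rate uncertainty, not method choice, is the
  question.
* The IQR outlier rule assumes roughly unimodal per-tree flux
  distributions; on strongly bimodal diel cycles it can clip genuine
  extremes.
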