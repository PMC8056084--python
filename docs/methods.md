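# Methods

This note documents the models implemented in `basilight`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Photometric accounting

Spectra are spectral photon flux densities (µmol m⁻² s⁻¹ nm⁻¹) on the
instrument's native wavelength grid. Band integrals (PPFD₇₀₀ over
400–700 nm, PPFD₈₀₀ over 400–800 nm) use the trapezoid rule on that grid
with the band edges inserted by linear interpolation — exact for
piecewise-linear flux, and no resampling step that could move photons
between bands. Unit conversions are linear maps: PPFD × photoperiod →
daily light integral (DLI, mol m⁻² d⁻¹), and DLI × 0.219 MJ mol⁻¹ →
daily energy. The 0.219 factor is the standard PAR energy content for
broadband horticultural spectra; since the same factor is applied to
natural and supplemental light on both bands, efficiency *comparisons*
are insensitive to its exact value, though absolute LUE numbers scale
with it.

The red:far-red ratio defaults to the 10 nm bands 655–665 nm over
725–735 nm (the narrow-band convention of the phytochrome literature);
both bands are configurable. Greenhouse transmission is the arithmetic
mean of daily inside/outside PPFD ratios — the literal "average of the
daily ratios" reading rather than a ratio of sums; for stable conditions
the two differ negligibly.

## Canopy light absorption and thermal time

Daily absorbed light per plant is Beer–Lambert,
Q_daily = I·(1 − e^(−k·LAI)), with a single extinction coefficient
k = 0.8 shared across treatments and seasons (configurable), and
LAI = leaf area / 0.002025 m², the fixed ground area per plant at the
experimental planting density. I is the *combined* natural + supplemental
daily energy for the chosen band: the band-matched natural DLI plus the
plant's supplemental PPFD held for the 18 h photoperiod, both converted
to MJ. There are no within-day dynamics; a day is the atomic light unit.

A useful identity (used as the test oracle): splitting the canopy into m
equal layers and attenuating transmitted light multiplicatively by
e^(−k·LAI/m) per layer gives total absorption identical to the one-shot
formula for every m. The implementation is checked against this layered
computation to 10⁻¹⁰ over a grid of I, LAI and k.

Thermal time is the developmental clock for leaf growth:
daily increments max(0, T_mean − 11 °C), accumulated. The 11 °C base is
the published basil value and the default.

### Leaf-area interpolation

Leaf area is destructive to measure, so the daily course is
reconstructed from anchors: a seedling leaf area at day 0, the
intermediate-harvest measurement, and (for final-harvest plants) the
final measurement. The three log-transformed anchors are fitted with one
regression of ln(LA) on thermal time (equal weights) and back-transformed
to an exponential. If the back-transformed prediction at either measured
anchor deviates from the measurement by more than 25 % relative error —
evaluated on the natural scale, rule firing if *either* anchor exceeds
the threshold — the trajectory is replaced by two exact log-linear
segments (start→intermediate, intermediate→final), which reproduce both
measurements exactly. The threshold is configurable; ∞ disables the
fallback.

Two decisions deserve note:

* **The day-0 anchor is not literal zero.** A zero leaf area has no
  logarithm; the treatment starts from transplants, not bare seed. The
  day-0 anchor defaults to 0.5 cm² (5·10⁻⁵ m²), a typical basil seedling
  at transplanting, and is configurable. The trajectory is insensitive
  to this choice in Q_total terms because early absorption is tiny.
* **Final-harvest plants borrow their middle anchor.** Each final plant's
  intermediate anchor is the leaf area of the dose-matched
  intermediate-harvest plant at the same gradient position (the mirrored
  gradient supplies exactly one such partner). Plants without a partner
  fall back to a two-anchor exponential, with a warning.

Intermediate-harvest plants have only two anchors (day 0 and their own
measurement) and use the exact exponential through them.

## LUE and EUE

LUE = DW / Q_total in g per MJ m⁻², following the convention that DW is
the per-plant shoot dry weight (g) while Q_total is per unit ground area
(MJ m⁻²); absolute values therefore depend on the planting density
embedded in the ground-area constant.

EUE relates growth to *electrical* energy: EUE = (DW_SL / SL) · μ, with
μ the lamp's light-output-per-electricity efficacy (0.37 blue, 0.63 red,
0.37 white+far-red — red LEDs are roughly 1.7× more efficient
electrically, which is exactly the factor by which EUE exceeds that of
an equally grown blue-lit plant). DW_SL, the dry weight attributable to
the supplemental light, is not directly measurable; it is defined here
from the cell's fitted dry-weight dose-response as
prediction(dose) − prediction(0) on the natural scale, divided by the
ground area. This is an interpretation — any definition that separates
the lamp's contribution from the sun's requires a model — and it is the
main caveat attached to absolute EUE values.

## Stage 1: dose-response fitting

Within one replicate × color × season × harvest cell, every plant has a
distinct dose, so a curve is estimable from a single treatment.
Responses are natural-log transformed and doses square-root transformed
(variance stabilisation; approximate linearity), giving
ln(trait) = a + b·√dose fitted by OLS. Plants with non-positive trait
values (e.g. no internodes formed) are excluded from the log fit and
counted on the fit object; cells failing entirely surface as explicit
missing rows, never silent drops.

The saturating alternative is monomolecular on the same transformed
scale: ln(trait) = A − B·e^(−r√dose), r > 0. With r fixed the model is
linear in (A, B), so r is *profiled*: an 80-point log-spaced grid of r
(scaled to the dose range, from near-linear r·√dose_max = 10⁻⁵ up to 50)
with exact OLS at each candidate, followed by a bounded scalar polish
around the grid minimum. The search is deterministic and start-free, and
because the straight line is the r → 0 limit of the family, the
monomolecular RSS never exceeds the linear RSS beyond numerical
tolerance (10⁻⁴ relative, enforced).

Model choice uses the extra-sum-of-squares F-test,
F = (RSS_lin − RSS_mono)/(RSS_mono/(n−3)) against F(1, n−3), selecting
the monomolecular curve at p < 0.05. Two properties matter for
interpretation:

* The two models are not strictly nested (the line lies only on the
  closure of the monomolecular family), so the 1-df reference is a
  pragmatic convention, not an exact distribution.
* With a clearly positive slope the family can only bend *toward
  saturation* (positive slope forces B > 0, hence concave curvature), so
  under a truly linear response the comparison is effectively one-sided
  and **conservative**: the test suite measures a selection rate of
  roughly half the nominal 5 % at the study conditions (slope 0.15,
  σ = 0.2, n = 120), while for a flat response (slope ≈ 0), where both
  curvature directions are reachable, the rate sits near nominal. In
  practice this means spurious saturation calls are rarer than α
  suggests; genuinely saturating responses are still detected with very
  large F values.

## Stage 2: the efficiency model

Each cell's slope (efficiency) and intercept (magnitude) feed the mixed
model y = color + season + harvest + two-way interactions + RS + RSC +
RSCH + e, where the random terms are the randomization units:
replication within season, within season-by-color, and within
season-by-color-by-harvest. With one coefficient per cell — the design
analysed here — RSCH is confounded with the residual, so any REML fit is
singular at that stratum. The package therefore treats the balanced
complete table as what it is, a split-split plot, and uses its **exact**
stratum F-tests: season against replication-within-season (3, 4 df),
color and color:season against the replication-by-color stratum
((2, 8) and (6, 8) df), harvest and its interactions against the
residual (18 df denominator). For balanced data these coincide with the
Satterthwaite degrees of freedom a REML fit would produce, without the
approximation. The implementation is verified against base R's
`aov(... Error(rep:season/color))` on seeded data to 10⁻⁶.

Variance components for RS and RSC are additionally estimated by REML
(statsmodels MixedLM); RSCH is reported as confounded with the residual.
Unbalanced tables (failed stage-1 cells) drop to a REML fit with Wald
chi-square tests, flagged in the result's notes — no imputation.

Marginal means are level means (equal to least-squares means under
balance) with standard errors from the factor's own error stratum;
pairwise comparisons use the studentized range (Tukey) at α = 0.05 and
are summarised as compact letters via insert-and-absorb. α is fixed at
0.05 throughout.

A robustness caveat: the stratum F-test assumes Gaussian errors within
strata. If color labels are permuted on records that carry a *large*
true color effect, the permuted marginal distribution is a well-separated
mixture and the small-denominator-df F-test can be mildly anticonservative
against its nominal level. Calibration checks in the test suite therefore
permute labels on records whose color assignment is genuinely
exchangeable (color effect configured to zero), which is the probe of the
test's size.

## The synthetic-data generator

Defaults encode the study design: gradient 230 → 0.5 µmol m⁻² s⁻¹ over
120 positions (exponential decay in position; linear and inverse-square
options), 18 h photoperiod, 3 colors × 4 seasons × 2 replications × 2
harvests, seasonal mean temperatures 19.3/20.6/24.4/24.1 °C, mean
natural DLIs 7.1/9.8/15.7/13.8 mol m⁻² d⁻¹ and period lengths 18/32,
20/28, 15/29, 14/33 days to the intermediate/final harvest. Natural
DLI₈₀₀ is DLI₇₀₀ × 1.25, a representative solar 700–800 nm photon
content; real-data users supply both columns directly. Lamp spectra are
synthetic Gaussian-band templates (blue 440+470 nm, red 660 nm,
white+far-red with the far-red band scaled to an R:FR of exactly 0.1),
normalised to unit PPFD₇₀₀.

Daily environments draw Gaussian temperatures (SD 1.5 °C) and lognormal
day-to-day DLI multipliers (CV 0.3) that are **normalised to mean one
over the period**: the configured seasonal mean is an observed summary,
and the simulation conditions on it, so realised period means match the
targets exactly rather than merely in expectation.

Phenomenological mode draws each primary trait (leaf/stem dry weight,
leaf area, hypocotyl/epicotyl/internode length) from
ln(y) = α + β√dose + rep effect + ε with ε ~ N(0, σ²), σ = 0.2 on the
log scale, per-color slopes (blue lowest, red and white+far-red similar
and higher — slopes around 0.06–0.10 per √µmol for weights) and additive
seasonal offsets (so color × season interactions are zero by
construction). Fresh weights derive from a lognormal dry-matter content
(mean 8 %), and all derived traits (shoot weights, plant height, LMA,
stem:leaf ratio) are built from their components, so the observation
table satisfies its consistency invariants identically. Replication
effects are random intercepts (SD 0.05 log units) per replication ×
season, the RS stratum.

Mechanistic mode is noise-free and exists to make light accounting
*identifiable*: leaf area grows exponentially in thermal time from the
seedling anchor to a dose-dependent final target, and shoot dry weight
is exactly LUE_true × Q_total with Q_total computed from the simulated
daily light by the same Beer–Lambert step the pipeline uses. Because the
pipeline re-derives the leaf-area trajectory from the *anchors* (an
independent reconstruction), recovering LUE_true to machine precision is
a genuine end-to-end check of the light-accounting chain, not a tautology.

What the generator does **not** emulate: photomorphogenetic mechanism
(color effects are parameter offsets, not phytochrome dynamics),
within-day light fluctuation, border effects or canopy re-spacing after
the intermediate harvest, measurement error structure beyond lognormal
noise, and any real site's day-to-day weather correlation (days are
independent). Tests passing on synthetic data therefore demonstrate the
*statistical machinery* — unbiased slope recovery, calibrated tests,
exact efficiency accounting — not the biological fidelity of any
particular parameter value.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full design (5760
plants per simulated experiment) for single analyses, 500 Monte-Carlo
replicates for slope-recovery checks, 1000 simulations for
model-selection calibration, 100 datasets × 10 permutations for stage-2
calibration, and 200 simulated experiments for the power check — sizes
chosen so the whole suite completes in a few minutes while keeping
Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

* Absolute LUE/EUE values inherit the fixed ground-area constant and the
  0.219 MJ mol⁻¹ factor; comparisons across treatments are robust to
  both, absolute levels are not.
* DW_SL is model-defined (dose-response prediction difference), not
  measured.
* The k = 0.8 extinction coefficient is a literature assumption shared
  across colors; real canopies under different light quality may differ
  in architecture and hence k.
* Band-800 analysis scales each plant's dose by the lamp spectrum's
  PPFD₈₀₀:PPFD₇₀₀ ratio; it assumes the spectral shape is constant along
  the gradient.
* The stage-2 exact F-tests require the balanced complete design; with
  missing cells the Wald fallback is asymptotic and its small-sample
  behaviour is not calibrated here.
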