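# Methods

This note documents the models behind `savagb`, the choices made where the
design was genuinely open, and what the synthetic data do and do not
establish.

## Wood density

Basic wood density is oven-dry mass over *fresh* cylinder volume of an
increment core (`rho = 4 dMS / (pi d^2 L)`, bit diameter 0.5 cm by
default). One core is treated as one tree. Species summaries use the
sample (n−1) standard deviation and report the standard error of the mean,
`sd/sqrt(n)`. Densities above 1.5 g cm⁻³ are physically implausible for
wood and are flagged with a warning but kept — rejecting them silently
would hide data-entry errors from the user.

## Stem volume, biomass and the BEF

Stems are measured in three sections (base → breast height at 1.3 m →
2.3 m → crown base); each section is a cone frustum parameterised by its
end girths. All lengths enter in cm so that `rho V / 1000` with `rho` in
g cm⁻³ yields kg directly; heights supplied in metres are converted.

Total dry biomass of a harvested tree sums fresh component masses (stem,
branches, foliage) scaled by their subsample dry:fresh ratios. The biomass
expansion factor `BEF = Btot/Bstem` is regressed on `ln(Bstem)` by
*unweighted* OLS (nothing suggests the calibration trees deserve unequal
weights). A BEF–DBH variant is provided; the two are compared by AICc
(both have three parameters, so the comparison reduces to likelihood),
but the ln-Bstem model is the pipeline default. BEF values below 1 warn
rather than fail: measurement noise can produce them on real data.

## Allometric models

AGB is gamma-distributed around a log-link mean in untransformed DBH (cm),
height (m) and wood density (g cm⁻³): the gamma family captures the
right-skew and variance-growing-with-mean behaviour of tree biomass while
the log link keeps predictions positive. Model types nest by measurement
effort: I (DBH), II (DBH, H, DBH:H), III (adds rho and its two-way
interactions). Quadratic terms and the three-way interaction are never
included.

Backward elimination removes, at each step, the candidate whose removal
lowers AICc the most, provided the drop is at least 2 (smaller differences
do not distinguish models); interactions are candidates first, the rho
main effect only once no rho interaction remains, and the intercept, DBH
and H mains are never removed (marginality is thereby respected). The
selected model's AICc can therefore never exceed the full model's.
Elimination is data-dependent: on small samples an inert predictor
survives whenever its likelihood-ratio deviate happens to be large, which
is a property of information-criterion selection, not of the
implementation.

Two likelihood conventions coexist deliberately. Coefficient standard
errors use the Pearson-estimated dispersion (coefficient estimates are
dispersion-invariant). The log-likelihood entering AIC/AICc is the full
gamma likelihood maximised over the shape parameter (a bounded 1-D
optimisation), and the parameter count k includes that shape parameter.
AICc = AIC + 2k(k+1)/(n−k−1) is undefined for n ≤ k+1 and raises.

Fit quality: explained deviance `1 − D/D0` against the intercept-only
model, and Nagelkerke's pseudo-R² (Cox–Snell rescaled by its ceiling).
Predictions outside the model's DBH validity domain are returned but
flagged, leaving the extrapolation decision to the caller.

## IVI

Relative density is the stem share (the common sampled-area denominator
cancels), relative frequency the plot-presence share normalised over
species, relative dominance the basal-area share with basal area
`pi DBH²/4` summed over stems — the standard Curtis convention, since
"dominance" admits alternatives. Ties in the ranking break
alphabetically so the table is order-invariant. Species covered by a
dedicated external equation (the two palm species) and the very sparse
baobab are excluded before normalisation, so IVI still sums to 300 over
the remaining species.

## Upscaling

Plot density is summed tree AGB (kg) /1000 / plot area (ha). Trees of
hook species are routed to a user-supplied callable (none is hard-coded:
published palm equations are accepted as callables, not re-implemented).
Class summaries report mean, SE = sd/√n, percent error
`100 · z · SE/mean` with z = 1.96 — i.e. the half-width of the ≈95 %
confidence interval relative to the mean, which is the convention that
reproduces the built-in published percent errors — stock `mean × area`
and stock SE `SE × area`. Published stock SEs are not internally
consistent with any single propagation rule, so the package always
derives its own. Group totals sum member stocks with SEs combined in
quadrature (plots are sampled independently per class). The density map
assigns each cell its class mean, preserving nodata (−9999); integrating
the map over cell areas reproduces the class-sum stocks to ≤1e−6
relative, which the tests assert.

## NDVI stratification

NDVI is `(NIR − Red)/(NIR + Red)`, NaN where both bands are zero; the
composite is the per-pixel NaN-aware mean over dates. The 0–255 stretch
is the linear min–max form with half-up rounding (a constant raster
raises). Stratification runs k-means on the composite value alone with 10
restarts and a fixed seed; labels are renamed in order of cluster centre
so they are stable. Sampling draws pixel centroids (cell centres in map
coordinates) without replacement per stratum; calibration and validation
draws are disjoint by construction, and an under-populated stratum
returns all its pixels with a warning.

## Synthetic data — what it emulates and what it does not

The generators default to the study conditions: the 15-species wood-
density table (means, SEs, core counts), per-category DBH validity ranges
and sample sizes (25/181/178/63/90; a config switch rescales to a 270-tree
total), 30×30 m / 100×100 m / 10×20 m plot sizes with the published plot
counts and class areas, and the BEF line 1.24155 + 0.14701·ln(Bstem) with
Gaussian noise (sd 0.05). Destructive stem masses are drawn log-uniformly
over 4.4–77.4 kg — the interval obtained by inverting the reported BEF
range 1.46–1.88 through the line — which also reproduces the reported
mean BEF of ≈1.67 in expectation.

Choices the study design left open, fixed once here: DBH is truncated
log-normal on the category range (log-mean in the lower third of the
range, right-skewed as real inventories are); height follows
`H = 1.5 · DBH^0.6` with log-normal noise (sd 0.1); girth tapers
geometrically (ratio 0.8) across the three sections; destructive totals
split 80/20 between branches and foliage (only the total/stem ratio
matters downstream); landscape NDVI class means are equally spaced in
[0.15, 0.75] with sd 0.02 over 6 dates.

A single master seed feeds per-operation substreams, so a fixed seed
reproduces every table byte for byte while operations stay independent.

What passing tests show: the estimators recover known generating
parameters, the pipeline's arithmetic is exact, and the published
in-paper arithmetic (sampled area, area percentages, stock totals,
percent-error convention) is reproduced. What they do not show: the
generators contain no species–site covariance, no measurement bias, no
allometric misspecification and no classification error, so parameter
recovery here does not certify accuracy on real field data.

## Problem sizes

Default test and acceptance runs use the study-scale sample sizes
(13-tree destructive campaigns, 537-tree inventories, 300-tree GLM
fixtures, grids up to 40×40, 50 Monte-Carlo seeds for the BEF and 20 for
GLM recovery); the full suite runs in a few seconds on one CPU.

## Known limitations

- The gamma GLM enters predictors untransformed; data whose mean is a
  power law in DBH are approximated, not matched, on the log-link scale.
- Percent errors assume approximate normality of the plot mean; with few
  plots per class (the published design has as few as 8) the 1.96
  multiplier is optimistic.
- Group-stock SEs assume independence across classes.
- One core per tree: within-tree density variation is not modelled.
- Raster I/O is single-band ESRI ASCII grid; no projection metadata
  beyond the origin/cellsize header.
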