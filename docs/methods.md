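# Methods

## Problem and pipeline

The package estimates winter-wheat leaf water content (LWC, percent of fresh
leaf mass) from 350–2500 nm canopy reflectance sampled at 1 nm. The workflow
is the standard chemometric chain for field spectroscopy:

1. mask atmospherically unreliable bands;
2. either optimise a two-band spectral index against LWC, or screen
   characteristic bands (CA / x-Lw) and fit a multivariate regressor;
3. evaluate on a held-out season with R², RMSE and RPD.

All reflectance is held internally as a unitless fraction in [0, 1]; percent
appears only at CSV boundaries. Ratio-type indices are invariant to that
choice, but difference indices and derivatives are not, so a single internal
convention removes a whole class of factor-of-100 errors.

## Band masking

Excluded windows: 1350–1400, 1800–1950 and 2450–2500 nm (atmospheric
water-vapour absorption). An excluded interval (a, b) drops wavelengths with
a < λ ≤ b — the lower endpoint is retained. On the 2151-band instrument grid
this keeps exactly 1901 bands, consistent with the full-band count used in
the model-comparison stage. A fully inclusive convention would keep 1898; the
half-open one is the convention this package commits to. Masking is
idempotent, and every downstream neighbourhood operation (derivatives,
extremum detection) treats the gap edges as segment boundaries rather than
reaching across them.

## Derivatives

First derivatives use central differences on the interior of each contiguous
grid segment and one-sided differences at segment ends (units: reflectance
fraction per nm). On a 1 nm grid the central-difference error for smooth
spectra is far below instrument noise; no smoothing is applied before
differentiation.

## Two-band index search

For each pair of retained bands the generic index (NDVI/RVI/DVI form) is
computed per sample and R² is the squared Pearson correlation with LWC —
identical to the coefficient of determination of a univariate linear fit of
LWC on the index. Undefined samples (zero denominators) are excluded pairwise
per cell; a cell needs at least 3 valid samples and a non-degenerate index
variance (absolute variance floor 1e-24, which only constant-by-construction
columns reach) or it is reported missing. The normalized and difference forms
are antisymmetric in (λ₁, λ₂), so the search computes the upper triangle and
mirrors it; the ratio form is evaluated over all ordered pairs. Hotspot
extraction is a global ranked top-k with deterministic tie-breaks (larger R²,
then smaller λ₁, then smaller λ₂; symmetric forms report λ₁ < λ₂). No
connected-region segmentation is attempted — the scientific deliverable is
the best pair and its neighbourhood, which top-k already exposes.

The map is computed row-wise with vectorised correlation algebra
(two-pass centred sums with validity masks), which covers the full
1901-band grid (~1.8 M unique pairs per form) in well under a minute per form
on one CPU. A decimation helper provides coarser exploratory grids; the
shipped analyses and the acceptance script use a 4 nm stride (476 bands,
~113 k pairs per form), which resolves hotspot positions to the width of the
absorption features being sought.

## Literature index catalogue

Ten published water indices plus the three optimised generic forms at
(1185, 1307) nm make the 13-entry catalogue. Three of the published formulas
circulate with typographical defects: an NDWI mixing 820 and 860 nm between
numerator and denominator, an hNDVI whose numerator and denominator are
identical (≡ 1), and an NDII mixing 1649 and 1679 nm. The catalogue computes
the forms from the original citations — NDWI = (R860 − R1240)/(R860 + R1240),
hNDVI = (R900 − R680)/(R900 + R680), NDII = (R820 − R1649)/(R820 + R1649) —
because the printed variants are degenerate or internally inconsistent.
`as_printed=True` reproduces the printed variants for anyone auditing the
difference. Undefined values propagate as flagged NaN with a count, never as
silent row drops.

## Characteristic-band screening

**CA.** Per-band Pearson correlation r between reflectance and LWC; the
screening seeds are the local peaks of |r| (the crests and troughs of r — a
trough of |r| is a correlation *zero-crossing*, which is not a water-sensitive
band, so |r| minima are deliberately not seeds). Extremum detection uses a
sliding window (default 10 bands ≈ 10 nm at full resolution, chosen to
suppress noise-level wiggles at the instrument's spectral resolution): an
interior index is a peak when it strictly exceeds everything in the window to
its left and is ≥ everything to its right, so plateaus report their leftmost
index and peak/trough sets swap exactly under negation. If the seeds exceed
the target count (default 100), the largest-|r| seeds are kept; if they fall
short, remaining bands are added in |r| order subject to a minimum spacing
(default 2 band positions) from already-selected bands, with a final
spacing-free fill only if candidates are exhausted. Every tie breaks toward
the smaller wavelength, making the selection fully deterministic.

**x-Lw.** A PLS1 decomposition (NIPALS, via scikit-learn's `PLSRegression`,
centred, no unit-variance scaling) of spectra against LWC. For each of the
first n components (default 3, or the cross-validated RMSEP minimum via
`best_n_components`), the x-loading-weight vector's peaks and troughs are
collected and the union returned. Each weight vector is sign-fixed so its
largest-magnitude element is positive — PLS component signs are otherwise
arbitrary, and the fix makes peak/trough positions reproducible across runs
and libraries. Per-component explained response variance is the incremental
R² of LWC on the (orthogonal) X-score sequence, so the percentages are
non-negative and total ≤ 100. RMSEP uses leave-one-out or seeded 5-fold CV.

Both methods run on masked spectra only; selected bands can never lie inside
an exclusion window.

## Regression models

* **PLSR** — component count at the leave-one-out RMSE minimum, capped at
  min(20, n − 2); numerical ties (noise-free data gives RMSE ≈ 1e-15 at every
  count) resolve to the smallest count within a 1e-8 relative tolerance, a
  parsimony rule that keeps selection deterministic. A fixed component count
  can be requested instead.
* **RFR** — 500 trees, sqrt feature subsampling, bootstrap, fixed seed.
* **ERT** — 500 trees, sqrt feature subsampling, *no* bootstrap (each tree
  sees the whole training set) and randomised split thresholds. Without
  bootstrap the ensemble interpolates its training set, so calibration RMSE
  is ~0 and calibration RPD diverges; validation metrics are the informative
  ones for this model.
* **KNN** — Euclidean distance, k = 3 by default; optionally k ∈ 1..15 by
  seeded 5-fold CV.
* **Index SLR** — ordinary least squares of LWC on a single spectral index.

Predictors are not standardised: reflectance bands share units and scale, and
PLS centres internally. Feature matrices are column-ordered by ascending
wavelength. A fitted model stores its feature wavelengths and selects exactly
those columns from any spectra it predicts on, raising a missing-band error
if one is absent.

## Evaluation

R² = 1 − SSres/SStot on the split's own predictions (out of sample for
validation — this differs from squared correlation out of sample and can go
negative); RMSE in LWC percent; RPD = SD/RMSE with the sample (n − 1) SD,
config-exposed, adequate above 1.4. The comparison workflow splits by season
label (earliest calibrates, latest validates, middles warned and dropped),
screens bands on calibration data only by default (a pooled mode exists and
is labelled leaky), fits every model on every band set, and reports a
machine-readable table at full precision with a two-decimal text rendering.

## Synthetic canopy generator

A phenomenological shape model, not a radiative-transfer model (no
PROSPECT/SAIL): the pipeline needs controllable statistical structure, not
physical fidelity. Per sample:

```
R(λ) = vis(λ) + P·biomass·logistic(λ; 720, 15)·swir(λ) − dips(λ) + ε(λ)
```

* `vis` — 0.04 baseline plus a 0.04 Gaussian green peak at 550 nm (σ 30 nm);
* red edge — logistic rise centred 720 nm (width 15 nm) to a NIR plateau
  `P = 0.45 × biomass`;
* `swir` — smooth logistic decline (centre 1550 nm, width 250 nm) to 35 % of
  the plateau;
* `dips` — Gaussian absorption features at 970/1200/1450/1940 nm (σ 30/35/
  40/45 nm, relative depths 0.3/0.4/1.0/1.2) with depth
  `0.18 × (LWC/100) × biomass × relative depth`, i.e. linear in canopy water;
* `ε` — i.i.d. Gaussian noise, SD 0.005 reflectance;
* result clipped to [0, 1]; a configuration clipping more than half the bands
  is rejected as implausible.

LWC per sample = profile mean + cultivar×year random intercept (SD 1 %) +
residual (SD 1 %), truncated to (0, 100]. The default profile table is
unimodal in sampling date (peak at date 2, ten days after jointing-stage
irrigation), converges across treatments early season and separates late
season with w2 > w1 > w0, and is anchored to the field campaign's reported
LWC range (min ≈ 56, max ≈ 89, mean ≈ 79 %). Biomass =
1.0 + gain(treatment) × date-progression with gains 0.15/0.30/0.45 for
w0/w1/w2, so the NIR-plateau ordering w2 > w1 > w0 after grain filling
emerges by construction. All randomness flows from one seed through three
`SeedSequence` substreams (cultivar intercepts, residuals, spectral noise);
identical configs are bitwise reproducible.

What the generator does *not* emulate: soil background and view geometry,
the red-edge shift with chlorophyll, heteroscedastic instrument noise,
correlated residuals along wavelength, and any physically calibrated
reflectance magnitudes. Passing tests therefore demonstrate that the
machinery recovers a known water signal under the study's design — not field
accuracy on real canopies.

Two deliberate couplings matter for interpretation: dip depth is linear in
LWC × biomass (canopy water), not LWC alone, so exact LWC recovery from dip
depth holds only at constant biomass (the property is tested under a
constant-biomass config); and biomass correlates negatively with LWC late in
the season, which is precisely why the season-transfer evaluation is the
meaningful test rather than within-season fits.

## Problem sizes

The shipped analyses use the full 252-sample design with a 4 nm search grid
(476 retained bands) for the pair search and model comparison, and an 8 nm
grid for the bit-for-bit reproducibility check; the exhaustive 1 nm search is
available through the same API (`decimate` step 1) and the CLI `--stride 1`.

## Known limitations

* The CA rule's target count (default 100) is a parameter, not a derived
  quantity; with smooth noise-free curves the seeds alone can be far fewer,
  and the top-up rule then controls the remainder.
* The x-Lw count depends on the extremum window and the noise level of the
  loading-weight curves; on the default synthetic data it selects ~90 bands
  on the 4 nm grid — fewer than CA's 100, but not matched to any particular
  field count.
* RPD is reported as computed even when a model interpolates its training
  data (ERT), where calibration RPD is meaninglessly large.
* Year labels sort lexically; the split assumes `YYYY-YYYY` season labels.
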