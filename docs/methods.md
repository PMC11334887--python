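# Methods

## Measurement model

A backlit 96-well plate is photographed; each well's signal is the mean
RGB intensity over a circular region of interest. The response variable is
the blue-channel mean (B-value) because the CBBG–protein complex absorbs
red/orange and transmits blue: B rises linearly with protein concentration
over the working range (0–20 μg/mL in the diluted analyte), while R and G
fall mildly. Absorbance from a plate reader can be substituted for the
B-value everywhere (`channel = "absorbance"`); the math is identical.

**ROI rule.** A pixel at integer coordinates (px, py) belongs to the ROI
when `(px−cx)² + (py−cy)² ≤ r²` (closed disk, no anti-aliased partial
pixels). This rule is deterministic and matches a brute-force enumeration
oracle exactly, which the tests exploit. Circles must lie fully inside
the image (centers range over `[0, W−1] × [0, H−1]`); an ROI containing no
pixel center is an error, not a zero. Two-click designation defaults to
*center + circumference point*; diameter-endpoint semantics are available
via `semantics="diameter"`. Images are used as stored 8-bit sRGB — no
gamma linearization or white-balance correction — because the assay
calibrates per plate, so any monotone sensor mapping is absorbed by the
standard curve; EXIF orientation is applied before coordinates are read.
Channel means are carried unrounded; tables display two decimals.

## Calibration and inverse prediction

Ordinary least squares of response on concentration (blank included as the
0 μg/mL point; no blank subtraction). Metrics:

- `R² = 1 − SSres/SStot`, with `R² = 1` when both sums vanish (constant,
  perfectly fitted response);
- `RMSE = sqrt(SSres/n)` — denominator `n` rather than `n−2` so that a
  perfect fit reports exactly 0 for any n; `n−2` is available as an option;
- `rRMSE% = 100 · RMSE / mean(response)`. A relative RMSE can be
  normalized by mean, range or maximum; the mean-response denominator is
  this package's definition (configurable at fit time through the
  `rmse_denominator`/metric options), chosen as the most common convention.

Inverse prediction is `(y − b₀)/b₁`. Responses below the fitted blank give
negative concentrations; these are *flagged* (`below_blank`) rather than
clamped, so that replicate averaging remains unbiased near zero.

The calibrator is a scikit-learn `BaseEstimator` (`LinearCalibrator`),
so it composes with sklearn tooling; `fit_linear` and `inverse_predict`
are functional wrappers over it.

## Detection and quantification limits

Inputs are replicate responses of a blank and of a strictly decreasing
(two-fold by construction, `make_twofold_series`) dilution series. Each
level is compared with the blank by a **one-sided Welch two-sample
t-test** (unequal variances), direction given by the calibration slope
sign, at α = 0.05 by default. Welch was chosen because replicate variance
is not homogeneous across concentrations in colorimetric data; the test,
replicate count and α for this decision are free choices of the package.
The LOD is the lowest concentration such that *it and every higher level*
reject — an isolated rejection below a non-significant level cannot set
the LOD, which makes the estimate monotone in effect size. If no level
rejects the result is an error ("undetectable"); if every level rejects
the LOD is reported at the lowest tested level and marked censored ("≤").
LOQ is defined as exactly 3 × LOD. Degenerate all-constant inputs produce
an undefined (NaN) test statistic and count as non-significant.

## Quantification and QC

Replicates aggregate to mean, sample SD (n−1) and RSD% = 100·SD/mean
(undefined, and an error, when the mean is 0 with nonzero spread).
Outlier screening is **off by default**; when enabled it is Dixon's Q
(r₁₀ statistic, 3 ≤ n ≤ 7, critical values at 90/95/99% confidence,
at most one exclusion). Spike recovery is
`100 · (measured_spiked − measured_base) / added`; spiked extracts usually
exceed the calibration range, so the fold-dilution applied before staining
is a user-declared input (`protein_mass_mg(..., dilution_factor=...)`).
Dry-weight content is
`conc · (V_final/V_aliquot) · V_extract / m_sample · 10⁻⁴` g/100 g; dye
addition cancels because standards and samples are stained identically,
which is also why standards are expressed as pre-dye analyte
concentrations. Method comparison averages each method's *unrounded*
replicate SDs and reports per-sample mean differences against the first
method; rounding (half-up: content/SD/RSD to 1 decimal, recovery to
1 decimal with an integer summary, prices to 3 decimals) happens only at
display.

## Cost model

Exact rationals (`fractions.Fraction`) internally; unit algebra covers
mass (mg/g/kg), volume (μL/mL/L) and counts with hard-coded conversions.
Plate-shared items carry an explicit share denominator, default 91: a
96-well plate loses 5 wells to the calibration standards, and the
remaining samples share those costs. Currency is an opaque label (CNY in
the bundled table). The bundled reference table carries the vendor's
printed per-test prices alongside the raw columns; the report recomputes
each row and flags third-decimal disagreements. One row ("Centrifugal
tube, 50 mL") prints 0.008 while its raw columns give 36/250/91 ≈ 0.0016
(five tubes per plate would explain 0.008); the package reports both the
printed-price total (1.576) and the recomputed total (1.570) and flags
that row rather than silently preferring either.

## Synthetic plate generator

The generator emulates exactly what the analysis consumes: per-well mean
colors that are linear in concentration plus Gaussian noise, painted as
uniform disks on a bright uniform background and quantized to 8 bits.
Defaults are the reference smartphone response (intercept 113.25, slope
0.8118 intensity units per μg/mL for B; invented mild negative slopes for
R and G, baselines 180/160, irrelevant to the B-value analysis) with
noise SD 1.0 intensity units per well — a free choice, since no well-level
noise magnitude is published; 1 intensity unit ≈ 1.2 μg/mL of equivalent
concentration noise, which reproduces validation-like RSDs at the assay's
working concentrations. Noise is i.i.d. per well (the analysis unit is
the well mean); optional per-pixel texture noise is off by default.
Lighting presets shift intercepts and noise only (`poor`: −30 intensity,
2× noise; `outdoor`: +15, 1.5× noise, slight green cast) and are
calibrated only to keep the qualitative ordering "well-lit indoor fits
best" reproducible; under the default models fewer than 1% of well pixels
ever clip. All randomness flows through one explicit seed (default 0);
identical seeds give byte-identical images.

What the generator does **not** emulate: meniscus and shadow optics,
camera ISP processing (demosaicing, sharpening, JPEG artifacts),
illumination gradients across the plate, and pigment interference
(e.g. chlorophyll in plant extracts). Tests passing on synthetic plates
therefore validate the *software chain* — geometry, extraction,
statistics, bookkeeping — not the photochemistry or real-camera behavior.

## Numerical and design choices

- Quantization bounds: a zero-noise rendered well differs from its model
  color by at most 0.5 intensity units (round-to-nearest), the tolerance
  used in round-trip tests.
- Monte-Carlo unbiasedness (parameter recovery; full pipeline content
  recovery) is asserted within 3 Monte-Carlo standard errors over 200
  seeded replicates — the conventional band for a mean-zero check; a 1-SE
  band would reject a truly unbiased estimator about a third of the time.
  Problem sizes (200 seeds, 5 standards, triplicate samples, ≤32×32
  oracle images ×1000) keep the whole suite in a few seconds while
  leaving the Monte-Carlo SEs small.
- Welch t on constant data yields NaN; NaN p-values are treated as
  non-significant rather than errors, so a flat series cleanly reports
  "undetectable".
- Layout parsing is strict: duplicate wells, out-of-range addresses
  (beyond H12) and unknown roles are hard errors; the plate geometry is
  capped at 8×12.
- The CLI is deterministic given config + seed; runs log a 12-hex config
  hash, the seed and the package version. Exit codes: 2 input, 3
  schema/layout, 4 computation.

## Known limitations

- Single-channel linear calibration only; no weighted or four-parameter
  logistic fits, no confidence/prediction bands, no blank-SD (3σ/slope)
  LOD variant.
- No automatic well-grid detection or perspective correction: ROIs are
  user-supplied (or ground-truth-supplied for synthetic plates).
- The published per-sample content values of the reference dataset cannot
  be recomputed here because the underlying raw well readings are not
  public; the bundled validation summary carries only the published
  summary statistics.
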