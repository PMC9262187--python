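# Methods

## Problem and model

The package estimates shoot Na⁺ and K⁺ contents (mmol g⁻¹ dry weight) of
individual rice plants from side-view hyperspectral image cubes, using a
panel of six genotypes spanning a salinity-tolerance gradient (IR29, Pokkali
and four of their recombinant inbred lines: FL454, FL478, FL499, FL510), two
treatments (control, salinity) and five replicate plants imaged daily for 18
days.

The statistical core is univariate partial least squares regression: with
centred spectra X (n samples × p bands) and centred content y, NIPALS
iteratively extracts weight vectors wₐ ∝ Xᵀy, scores tₐ = Xwₐ, loadings
pₐ = Xᵀtₐ/tₐᵀtₐ and qₐ = yᵀtₐ/tₐᵀtₐ, deflating X ← X − tₐpₐᵀ after each
component. The regression vector for a components is
B = W(PᵀW)⁻¹q. PLSR is appropriate here because p ≫ n and neighbouring bands
are strongly collinear. X is centred but not variance-scaled: the spectra
(and their derivatives) share one physical scale, so scaling would only
amplify noisy bands.

Model selection mirrors the repeated random-split protocol: each iteration
draws a random half of the final-day samples (24 of 48) for training, fits
1–10 components, and evaluates the root mean squared error of prediction
(RMSEP) on the held-out half; the component count minimising RMSEP wins the
iteration, and the split with the lowest RMSEP overall wins the search.
Accuracy is reported as the squared Pearson correlation (R²) between
predicted and observed held-out values. When lowest RMSEP and highest R²
disagree across iterations, RMSEP is primary and R² breaks exact ties only,
since RMSEP is also the component-selection criterion. The winning model is
then applied to every plant-day spectrum to produce daily ion trajectories;
negative predictions are reported as-is and flagged, never clipped, because
they are a known and diagnostically useful failure mode of content
prediction near zero.

## Pipeline stages and defaults

**NDVI masking.** NDVI = (NIR − red)/(NIR + red) computed from the grid bands
nearest 615 nm and 1117 nm (positions 14 and 119 on the default 243-band
grid; nearest-neighbour lookup because the band centres are approximate).
Pixels with NIR + red = 0 get NDVI 0, so dark pixels never enter the mask.
The mask keeps pixels with NDVI strictly above a threshold, default 0.25 —
comfortably between background (≈ 0) and vegetation (≳ 0.5); an Otsu
histogram threshold is available as an alternative. Cropping takes the tight
bounding box of the mask (0-based, half-open, optional padding) and zeroes
non-plant pixels inside it; cropping never changes masked-pixel statistics.

**Mean spectra.** Per band, the mean over masked pixels. Default
`nonzero_only` averages only positive intensities, removing the plant-size
bias that zero-intensity pixels introduce; `zero_inclusive` is provided for
comparison. A band with no qualifying pixels yields 0.

**Gap-segment derivative.** At band i the first derivative is
(mean x[i+g … i+g+s−1] − mean x[i−g−s+1 … i−g]) / Δλ, where Δλ is the
wavelength distance between the two segment centres (= step·(2g+s−1) on a
uniform grid), so a spectrum linear in wavelength returns its slope exactly.
Each pass trims g+s−1 bands per edge; higher orders iterate the operator.
Defaults s = 5, g = 6 were fixed so the edge loss is 10 bands per side,
mapping 243 → 223 points (an 8.23% reduction); both are configurable.

**Q3 band filter.** Per band, the absolute difference between the salinity
and control row means; the threshold is the linearly interpolated (type-7)
third quartile of those differences and retention requires a *strictly*
greater difference. With 243 distinct differences exactly 61 bands (the top
25%) survive. The absolute value matters: a signed rule would silently
discard bands where control exceeds salinity. The filter is applied to the
raw 243-band matrix using all imaging days. A related published description
of this filter reports 67 of 243 bands and attaches the filter to the
smoothed dataset; that combination is arithmetically inconsistent with a
75% reduction of 243 bands, so this implementation keeps the
quartile-of-differences definition and documents the discrepancy here
rather than resolving it silently.

**Chemistry.** The flame-photometer standard curve is an ordinary
least-squares line through the six standards (40, 30, 20, 10, 5, 1 ppm);
readings invert to ppm via (response − intercept)/slope. Tissue content is
content = ppm · D · V / (M · m) with defaults D = 50 (0.1 mL sample + 4.9 mL
water), V = 0.010 L extract, m = 0.1 g tissue, M the molar mass (Na 22.99,
K 39.10 g mol⁻¹); e.g. 4.00 ppm Na⁺ ↦ 0.870 mmol g⁻¹ DW. Dry weight is
assumed for the mass basis. A "CV" accuracy statistic sometimes quoted
alongside R² for this protocol has no standard definition and is not
computed; the per-iteration RMSEP log serves that role.

## The synthetic experiment

The generator emulates the study's data-generating structure, not its
radiometry:

- **Silhouette** — a union of ellipses (one body, two tillers) with
  per-plant jittered geometry, growing linearly with day; deterministic
  given the seed and plant identity, so the silhouette area is exact truth
  metadata.
- **Reflectance** — plant pixels carry a shared vegetation baseline (low
  visible, red edge near 715 nm, NIR plateau ≈ 0.5, water dip at 1450 nm)
  plus *linear* loadings times the latent Na⁺ and K⁺ contents, a smooth
  per-plant perturbation uncorrelated with content, and i.i.d. Gaussian
  noise (sd 0.02 reflectance units), clipped at 0. The baseline is shared
  across genotypes so that, with the ion loadings zeroed, the spectra carry
  no back door from genotype identity to mean ion content — the no-signal
  control below is meaningful only under that choice. Background pixels are
  flat (0.18) so their NDVI ≈ 0 while plant NDVI ≈ 0.7, encoding the
  physical rationale for NDVI masking.
- **Trajectories** — under control, contents are constant per plant (a
  per-replicate offset, constant in time, provides biological variation
  without breaking monotonicity). Under salinity, Na⁺ rises linearly from
  day 4 with genotype-specific slopes ordered
  FL499 > IR29 ≈ FL454 > FL478 ≈ Pokkali > FL510 (0.065 down to
  0.018 mmol g⁻¹ DW per day, reaching ≈ 0.3–1.0 mmol g⁻¹ DW at day 18, the
  empirically observed range), and K⁺ declines from day 12 at
  0.05 mmol g⁻¹ DW per day from a 1.0 baseline. Contents are floored at 0.
- **Flame photometry** — the latent content is pushed backwards through the
  dilution chain to diluted-extract ppm, mapped to an instrument response on
  a configurable standard curve, and optionally perturbed with Gaussian
  reading noise; with zero noise the chemistry stage recovers the latent
  content to machine precision (a round-trip identity used as an invariant).

Default scale: 6 genotypes × 2 treatments × 5 replicates × 18 days = 1080
cubes of 243 × 64 × 64. Cubes are generated lazily from per-plant/day seed
streams, so the full experiment never resides in memory and any access order
is bit-reproducible.

What the generator deliberately omits: illumination and view geometry,
specularity, leaf angle and self-occlusion, genotype-specific spectra,
nonlinear content–reflectance responses, day-7 imaging gaps, and growth
differences between treatments. Passing parameter-recovery tests therefore
show that the pipeline is a correct estimator *when its linear-response
assumption holds and segmentation is easy* — they do not certify accuracy on
real imagery, where those omitted effects dominate the error budget.

## Study sizes and measurement design

Flame photometry is destructive, so the pipeline "sacrifices" 4 of the 5
replicates per genotype × treatment on the final imaging day for chemistry,
giving 48 modeling samples — the only count consistent with both a 5-plant
design and a 24-sample training half. The default search uses 2,000
iterations: the best-split RMSEP is within sampling noise of the
100,000-iteration value at a fiftieth of the cost, and the full-size search
remains available (`--full`, or `n_iterations=100_000`). Validation studies
in the test suite run the same structure with smaller images (24–32 px) and,
for the pipeline, a 4-day course with the Na⁺ rise starting at day 1; these
sizes are the package's chosen desk-scale defaults for routine verification.

## Numerical choices and degenerate inputs

- Nearest-band lookup breaks ties toward the lower index.
- An empty plant mask raises an explicit error (a failed segmentation must
  not silently produce an empty spectrum).
- NIPALS stops early if the residual covariance ‖Xᵀy‖ collapses (rank
  exhausted); requesting more components than min(n−1, p) or a
  zero-variance response is an error.
- R² is undefined for zero-variance predictions and raises at the metric
  level; inside the search such iterations are logged with R² = NaN and
  never win tie-breaks. Summaries treat NaN as "no linear association".
- Component-count ties in an iteration resolve to fewer components.
- The search derives nothing from global state: one generator seeded by the
  caller drives the split sequence, and pipeline sub-searches use seeds
  derived from the simulation seed via independent spawn keys.

## Limitations

- The linear latent→reflectance map makes PLSR exactly the right estimator;
  real reflectance responds nonlinearly and the achievable R² on real data
  is far below the synthetic ceiling.
- Best-of-many-splits selection is optimistically biased; the no-signal
  control (median best R² ≤ 0.2 with zeroed loadings across replicate
  simulations) bounds that bias under the default design but does not remove
  it. Reported best-split R² should not be read as an unbiased accuracy
  estimate.
- One plant per cube; no multi-plant separation.
- The K⁺ signal in short (< 12 day) simulated courses is replicate noise
  only, since the decline has not begun.
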