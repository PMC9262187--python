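# hsion

Hyperspectral prediction of tissue Na⁺ and K⁺ in salt-stressed rice.

Salinity tolerance screening in rice breeding panels traditionally requires
destructive tissue sampling and flame photometry to measure shoot Na⁺ and K⁺
contents. `hsion` implements the alternative: side-view hyperspectral image
cubes (243 bands, 550–1700 nm at 4.77 nm steps) are reduced to one mean
reflectance spectrum per plant per day, and partial least squares regression
(PLSR) relates those spectra to ion contents measured once, on the final day,
so that daily ion trajectories can be *predicted* non-destructively for every
plant. The package is aimed at plant phenomics researchers who want a tested,
reproducible reference implementation of this pipeline, complete with a
synthetic experiment generator for validation.

## The pipeline

1. **Imaging** — plant pixels are separated from background with an NDVI mask,
   NDVI = (NIR − red)/(NIR + red), built from the ~615 nm and ~1117 nm bands;
   the cube is cropped to the plant and per-band mean pixel intensities
   (non-zero pixels by default, to avoid plant-size bias) form the plant's
   reflectance spectrum.
2. **Preprocessing** — three modeling datasets: the raw spectra; a
   gap-segment first derivative (difference of two s-point segment means
   separated by a gap g, divided by the wavelength distance between segment
   centres; defaults s = 5, g = 6 trim 10 bands per edge, 243 → 223); and the
   subset of bands whose |salinity mean − control mean| exceeds the third
   quartile of the per-band difference distribution (243 → 61 when the
   differences are distinct).
3. **Chemistry** — flame-photometer calibration (least-squares standard curve
   over 1–40 ppm) and the unit chain
   content = ppm · dilution · V / (M · m) converting diluted-extract ppm to
   mmol g⁻¹ DW (defaults: 1:50 dilution, 10 mL extract, 100 mg tissue).
4. **Modeling** — univariate NIPALS PLSR. Model selection repeats a random
   half/half split (24 of 48 final-day samples), picks the component count
   (≤ 10) minimising held-out RMSEP, and keeps the best split over many
   iterations; the winning model predicts daily ion content for all plants.
5. **Synthetic data** — a generator producing cubes in which plant-pixel
   reflectance is a vegetation baseline plus *linear* responses to latent Na⁺
   and K⁺ contents plus Gaussian noise, with genotype-ordered Na⁺ accumulation
   under salinity and a shared K⁺ decline from day 12. Because the latent
   truth is returned, the whole pipeline is testable as a parameter-recovery
   problem.

## Worked example

Simulate the final imaging day, extract spectra through the NDVI path, smooth
them, and run a 2,000-iteration repeated-split search for Na⁺:

```python
import pandas as pd
from hsion import (SimulationConfig, SpectraMatrix, extract_spectrum,
                   repeated_split_search, simulate_experiment, smooth_matrix)

cubes, truth = simulate_experiment(SimulationConfig(seed=7), days=[18])
spectra, rows = [], []
for key in cubes:
    genotype, treatment, rep, day = key
    if rep > 4:          # 4 replicates measured -> 48 modeling samples
        continue
    spectra.append(extract_spectrum(cubes[key]))
    rows.append({"genotype": genotype, "treatment": treatment,
                 "day": day, "replicate": rep})
raw = SpectraMatrix.from_spectra(spectra, pd.DataFrame(rows))
smoothed = smooth_matrix(raw)
print("raw bands:", raw.n_bands, "-> smoothed bands:", smoothed.n_bands)

y = raw.annotations.merge(
    truth.records, on=["genotype", "treatment", "day", "replicate"]
)["na_content"].to_numpy()
print(repeated_split_search(smoothed, y, n_iterations=2000, seed=7).summary())
```

Output:

```
raw bands: 243 -> smoothed bands: 223
Repeated-split PLSR model search
==============================================
Iterations:                 2000
Training samples:           24
Best iteration:             1673
Best components:            6
Best held-out RMSEP:        0.00360457
Best held-out R^2:          0.9999
```

The smoother maps each 243-band spectrum to 223 derivative points; the search
trains on a random half (24 samples) per iteration and here recovers the
latent Na⁺ content almost perfectly (held-out RMSEP 0.0036 mmol g⁻¹ DW,
R² ≈ 1), as expected when the spectral response to ion content is linear and
pixel noise averages out over the plant mask.

The same study runs end to end from a shell:

```sh
hsion run --out study_out --seed 7 --iterations 2000
```

writing the three spectra datasets, band-filter table, per-ion models, daily
predictions and a summary table under `study_out/`.

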