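# grasspec

Estimation of grassland aboveground biomass from field-spectrometer canopy
reflectance: chemometric pre-processing, continuum-removal absorption
indices, and cross-validated regression model grids, with a synthetic
canopy-spectra generator for end-to-end testing.

## What it does

* **spectra_io** — loads/validates delimited spectra tables (350–2,500 nm),
  averages repeated plot readings (mean/median), removes the noisy detector
  bands (1,360–1,385 nm, 1,800–1,930 nm, >2,400 nm) and restricts to the
  VNIR / VNIR+SWIR1 / VNIR+SWIR1+SWIR2 subsets.
* **transforms** — the 18 pre-processing transformations: baseline offset,
  1st–3rd-order de-trending, three multiplicative scatter corrections,
  five normalisations, Norris gap first derivatives (gaps 3/5/7/9),
  reflectance→absorbance and SNV.
* **continuum** — continuum removal over five absorption zones
  (Z1 440–567, Z2 554–762, Z3 916–1,120, Z4 1,079–1,297, Z5 1,265–1,676 nm)
  using the endpoint chord, plus the maximum band depth (MBD) and
  area-over-minimum (AOM = MBD × width at half depth) indices.
* **models** — from-scratch NIPALS PLSR (mean-centred, latent-factor count
  chosen by the strict >2 % cross-validated-RMSE reduction rule), OLSR, and
  linear ε-SVR (ε = 0.1, min-max scaling refit per fold, smallest C within
  2 % of the grid-best LOOCV RMSE), all under leave-one-out CV with
  R², RMSE and %RMSE statistics.
* **pipeline** — enumerates and runs the full model grid (140 specs per
  response variable; 420 over TAGB, GAGB and %GAGB), ranks models
  (R² descending, ≥2 % RMSE-improvement flags) and explores all 15 zone
  combinations containing Z4.
* **synthetic_data** — a parametric grass-canopy reflectance template with
  biomass-linked absorption-dip depths, per-plot multiplicative scatter and
  detector-dependent reading noise (30 plots × 15 readings by default,
  TAGB ~ N(45.05, 15.40) truncated, green fraction ~ N(68.34, 13.57)
  truncated), plus a recovery benchmark that runs the whole pipeline.

## CLI

```sh
grasspec simulate  --seed 1 --out-spectra spectra.csv --out-biomass biomass.csv --out-truth truth.csv
grasspec transform --code SNV --in spectra.csv --out snv.csv
grasspec features  --zones Z1,Z3,Z4 --in spectra.csv --out features.csv
grasspec fit       --method plsr --response TAGB --in predictors.csv --biomass biomass.csv
grasspec grid      --config grid.yaml --spectra spectra.csv --biomass biomass.csv --out results.csv
```

Spectra files are delimited text with a `wavelength_nm` first column and one
column per reading named `<plot_id>__r<k>`; biomass files have columns
`plot_id, TAGB, GAGB, pctGAGB`. `grid.yaml` / `sim.yaml` may override any
`GridConfig` / `SimulationConfig` field.

## Notes

* Raw field spectra for the original study were never deposited, so numeric
  results tables are not reproducible; the package instead verifies grid
  composition, analytic index geometry, transform identities, and
  parameter recovery on synthetic data (see `tests/test_acceptance.py`).
* Cross-validation is leakage-free by construction: centring, feature
  scaling and MSC reference spectra are recomputed inside every fold.
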