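# lipidir

FTIR chemometrics for microbial lipid phenotyping.

High-throughput transmission FTIR spectroscopy of dried yeast biomass is a
fast alternative to gravimetric lipid extraction and GC fatty-acid
analysis when screening oleaginous yeasts for single-cell-oil production.
`lipidir` implements the full calibration workflow for that setting:

* **preprocessing** — extended multiplicative signal correction (EMSC)
  with linear and quadratic baseline terms and up-weighted spectrally
  inactive windows, Savitzky-Golay second-derivative spectra (2nd-degree
  polynomial, window 9 or 15), replicate averaging and spectral-region
  extraction;
* **calibration** — PLS1 (NIPALS) regression of total lipid content
  (% of cell dry weight) and summed saturated / monounsaturated /
  polyunsaturated fatty acids (% of total fatty acids) against reference
  chemistry, with leave-one-biological-replicate-out cross-validation,
  deterministic factor selection and a seven-preset spectral-region
  evaluation (acyl C–H stretch 3100–2800 cm⁻¹, fingerprint 1800–700 cm⁻¹,
  carbonyl windows and their combinations);
* **profiling** — PCA score tables for the lipid / protein / carbohydrate
  regions, band intensities for the 16 canonical biomass bands, a
  free-fatty-acid indicator (A₁₇₁₀/A₁₇₄₅ > 1), an unsaturation index
  (A₃₀₁₀/A₂₉₂₅), and the total-lipid vs. fatty-acid-class
  cross-correlation matrix;
* **synthetic data** — a generator producing FTIR-like spectra with known
  biochemical ground truth and the screening design's replicate structure
  (13 strains × 4 substrates × 2 biological × 3 technical replicates),
  so every stage is testable end to end.

## Model

EMSC fits each measured spectrum *z* against a reference *m* on the
wavenumber axis *t* scaled to [−1, 1],

    z = a + b·m + d·t + e·t², corrected = (z − a − d·t − e·t²) / b,

removing additive baseline and multiplicative scatter. PLS1 extracts
latent factors by NIPALS deflation (w ∝ Xᵀy, t = Xw, deflate) and forms
the regression vector B = W(PᵀW)⁻¹q; model order is chosen from the
RMSECV curve of pooled out-of-fold predictions under
leave-one-biological-replicate-out cross-validation (one-standard-error
rule by default).

## Worked example

```sh
lipidir simulate --seed 3 --n-strains 3 --out sim/
lipidir crosscorr --reference sim/reference.csv
```

prints the Pearson cross-correlation of the reference chemistry:

```
             total_lipid     sat    mufa    pufa
total_lipid       1.0000 -0.0666  0.0263  0.0031
sat              -0.0666  1.0000 -0.8222  0.1684
mufa              0.0263 -0.8222  1.0000 -0.6208
pufa              0.0031  0.1684 -0.6208  1.0000
```

Total lipid content is essentially uncorrelated with the fatty-acid
profile (the generator draws them independently, and screens of real
strain panels show the same), while SAT and MUFA are strongly
anti-correlated because the classes are percentages of a common total.

A full run — both preprocessing strategies, all region presets per
response, PCA and band profiling:

```sh
printf 'seed: 7\nsimulate:\n  n_strains: 13\n' > run.yaml
lipidir run --config run.yaml --out run7/
lipidir report --run run7/
```

```
- **mufa**: best region `a` — R2_CV = 0.898, R2_Test = 0.919, RMSECV = 3.375, RMSE_Test = 3.072, 6 factors
- **pufa**: best region `a` — R2_CV = 0.941, R2_Test = 0.950, RMSECV = 1.636, RMSE_Test = 1.564, 9 factors
- **sat**: best region `a` — R2_CV = 0.870, R2_Test = 0.886, RMSECV = 3.497, RMSE_Test = 3.386, 4 factors
- **total_lipid**: best region `b` — R2_CV = 0.999, R2_Test = 0.999, RMSECV = 0.260, RMSE_Test = 0.223, 3 factors
```

Total lipid calibrates best on the combined acyl + fingerprint region
(preset `b`), the fatty-acid classes on the acyl C–H stretch region
(preset `a`) after second-derivative preprocessing; RMSE values are in
%CDW (total lipid) or % of total fatty acids (SAT/MUFA/PUFA). The report
also lists samples whose free-fatty-acid carboxyl band at 1710 cm⁻¹
overtops the triacylglycerol ester band at 1745 cm⁻¹.

The same estimators are available programmatically
(`lipidir.EMSC`, `lipidir.SavitzkyGolayDerivative`,
`lipidir.PLS1Regression` — scikit-learn-compatible transformers and
regressors) alongside `SpectrumSet`-level functions
(`fit_emsc`, `savgol_derivative`, `evaluate_regions`, ...).

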