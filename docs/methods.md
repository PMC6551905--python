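# Methods

## Scope and data model

`lipidir` calibrates lipid phenotypes of oleaginous yeasts from
high-throughput transmission FTIR spectra of dried biomass. Spectra live
in a `SpectrumSet`: a strictly descending wavenumber grid (cm⁻¹, the
instrument-export convention; ascending files are silently re-sorted), an
S×C absorbance matrix and per-sample metadata (strain, substrate P/G/X/M,
biological replicate, technical replicate). Reference chemistry — total
lipid in % of cell dry weight (CDW), and summed saturated (SAT),
monounsaturated (MUFA) and polyunsaturated (PUFA) fatty acids in % of
total fatty acids — is keyed by (strain, substrate, bio_rep). The
fatty-acid classes may sum to less than 100% (unidentified fatty acids);
sums above 102% are rejected, the 2-point tolerance absorbing GC rounding.

Grid spacing is taken from the file as-is; the synthetic generator uses a
uniform 2 cm⁻¹ grid over 4000–500 cm⁻¹ (1751 channels), a digitisation
consistent with a 6 cm⁻¹ optical resolution. Region intervals are closed
on both ends.

## Preprocessing

**EMSC.** Each spectrum z is regressed on [1, m, t, t²] where m is the
reference spectrum (default: the mean spectrum of the set) and t the
wavenumber axis affinely scaled to [−1, 1] — scaling keeps the polynomial
design well conditioned regardless of the cm⁻¹ magnitudes. The fit is
weighted per channel; by default the spectrally inactive windows
3700–3100 and 2700–1800 cm⁻¹ (no fundamental biomass bands) carry weight
10 against 1 elsewhere, anchoring the baseline estimate. Both the windows
and the weight are configurable, since reasonable instruments and
deposition protocols shift them. The corrected spectrum is
(z − a − d·t − e·t²)/b. Samples with fitted scatter factor b ≤ 10⁻⁸ are
flagged and returned uncorrected rather than divided by ~0. A constant
reference makes the design rank-deficient and is rejected with a named
error.

**Savitzky-Golay.** Derivatives are taken with respect to channel index
(on a uniform grid this is a constant rescale of d/dcm⁻¹, absorbed by the
regression). Edge channels are served by the polynomial fitted to the
terminal window (`scipy.signal.savgol_filter(..., mode="interp")`), so
grid length and alignment across samples are preserved. Both window
sizes in common use here (9 and 15 points) are supported; 9 is the
default.

**Strategies.** Strategy (a), used for total lipid: EMSC, then averaging
of technical replicates within biological replicates and of biological
replicates within (strain, substrate) — on the balanced design this
equals the grand per-condition mean. Strategy (b), used for the
fatty-acid classes: second derivative first, then EMSC against the mean
derivative spectrum with uniform weights. The derivative suppresses broad
baseline structure and, because second-derivative amplitude scales with
band sharpness, concentrates the signal in the narrow acyl bands — the
subsequent EMSC division by b then approximately normalises out the
absolute lipid amount, which is what makes ratio-type responses
(% of total fatty acids) nearly linear in the corrected channels.

## Calibration

PLS1 by NIPALS deflation, deterministic, X mean-centred only (channels
share units; autoscaling is deliberately off). The regression vector for
K factors is B = W(PᵀW)⁻¹q. Requested factor counts beyond the effective
rank stop early with a warning.

Cross-validation leaves one biological-replicate group — all technical
replicates of one (strain, substrate, bio_rep) culture — out per fold, so
technical replicates can never leak between training and validation.
RMSECV and R²_CV are computed from the pooled out-of-fold predictions.
The factor count is selected from the RMSECV curve; the default rule is
the one-standard-error rule (smallest K within one SE — over fold RMSEs
at the minimising K — of the minimum), a deterministic, parsimony-biased
replacement for the visual inspection a practitioner would do. A plain
argmin rule (ties toward fewer factors) is available.

The calibration/test split operates on biological-replicate groups
(never splitting a group), stratified by strain via largest-remainder
apportionment of round(n_groups·fraction) test groups; default test
fraction 0.25. With 70 groups this yields an 18-group test set.

Seven region presets are evaluated: (a) 3100–2800; (b) 3100–2800 +
1800–700; (c) 3100–2800 + 1800–1700; (d) 3100–2800 + 1715–1700;
(e) 3100–2800 + 1800–1715; (f) 1800–1700; (g) 1800–700 cm⁻¹. Total lipid
is restricted to (a) and (b); SAT/MUFA/PUFA use all seven. Note the
asymmetry between (d) and (e): the narrow 1715–1700 window actually
contains the free-fatty-acid carboxyl band (1710 cm⁻¹) and 1800–1715 the
ester band (1745 cm⁻¹), which is the opposite of what the ester/FFA
labels attached to these windows in the literature suggest; the presets
follow the numeric intervals as printed and the label ambiguity is noted
here rather than silently "fixed".

## Profiling

Band intensity is the windowed maximum within ±6 cm⁻¹ of the band centre
(6 cm⁻¹ = the optical resolution); a fixed rule rather than qualitative
peak reading makes the quantity testable. The FFA indicator offsets both
carbonyl bands by the local minimum of the 1800–1700 cm⁻¹ window and
flags samples with A₁₇₁₀/A₁₇₄₅ strictly greater than 1. The unsaturation
index is A₃₀₁₀/A₂₉₂₅ without offset. Cross-correlation is Pearson by
default (Spearman selectable); zero-variance columns produce NaN rows
with a warning instead of an exception.

## Synthetic data generator

The generator emulates the screening design — 13 strains × substrates
{P, G, X, M} × 2 biological × 3 technical replicates = 312 spectra — with
a latent truth per biological sample. (Published screens of this shape
sometimes report larger spectrum counts than the stated design implies,
e.g. 504; the generator follows the stated design.)

* **Truth.** Per strain a baseline lipid content U(8, 20) %CDW; substrate
  offsets P +0, X +U(4, 18), M +U(10, 26), G +U(18, 32), matching the
  observed ordering (pre-culture lowest, glucose highest, ~40/24/32%
  means for G/X/M) with per-condition jitter, clipped to [5, 60]. The
  fatty-acid composition is drawn independently of lipid content
  (sat ~ U(10, 45), pufa ~ U(2, 25), mufa = 0.85–0.98 of the remainder —
  MUFA-dominated profiles as GC data show, with an unidentified rest).
  FFA share of the lipid pool: U(0.25, 0.41) in pre-cultures,
  U(0.06, 0.28) under nitrogen limitation — the ranges thin-layer
  chromatography reports for such screens. Non-lipid biomass splits into
  protein/carbohydrate/phosphate loadings. Biological replicates add
  small jitter (lipid sd 1.5 %CDW, FA classes sd 1.2 points). Draws are
  hierarchical (strain → condition → replicate substreams), so enlarging
  the design does not perturb existing truth rows.
* **Components.** Pure spectra are Beer-Lambert linear mixtures of
  non-negative, max-normalised Gaussian-band components. Acyl chains get
  class-specific components sharing the canonical centres (2955, 2925,
  2850, 1465, 1380, 1155, 725 cm⁻¹; sd ~10 cm⁻¹) with CH₃/CH₂ amplitude
  ratios falling and the olefinic 3010 cm⁻¹ band rising with
  unsaturation (amplitudes ≈ 0 / 0.20 / 0.42 for SAT/MUFA/PUFA, i.e. the
  summed 3010 weight tracks mufa + 2·pufa, a double-bond proxy). A
  single shared acyl component scaled only by a 3010 band was considered
  and rejected: it would make the spectrum's only composition signal the
  scalar mufa + 2·pufa, leaving MUFA% fundamentally unidentifiable — real
  acyl spectra do differ by class, which is precisely why derivative
  spectroscopy can calibrate fatty-acid profiles. Carbonyls: ester band
  at 1745 cm⁻¹ (gain 0.6) vs. carboxyl band at 1710 cm⁻¹ (gain 0.9),
  mixed by FFA share. Protein (amide I/II/III, sd 25 cm⁻¹), carbohydrate
  (broad 1200–900 complex, sd 30 cm⁻¹) and phosphate components carry
  the non-lipid mass, so total lipid %CDW is a genuine shape property of
  the spectrum, as it is for real biomass films of comparable deposition.
* **Noise.** Per technical replicate: multiplicative scatter
  b = exp(N(0, 0.15)), additive offset/linear/quadratic baseline
  N(0, 0.02) on the scaled axis, a scalar replicate perturbation
  N(0, 0.01), and white channel noise N(0, 5·10⁻⁴ AU). The channel-noise
  default corresponds to a peak SNR of ~10³ at the ~0.5–1.5 AU main
  bands, the regime of 64-scan-averaged transmission measurements;
  second-derivative filtering amplifies white noise strongly, so this
  parameter dominates the difficulty of the fatty-acid calibrations.
  Zero noise reproduces the pure mixtures exactly, and the emitted
  reference table is exactly the truth (optional GC noise is off by
  default).

What the generator does **not** emulate: water-vapour and CO₂ lines,
Mie-type scatter dispersion, band-shape changes with physical state,
detector nonlinearity, or correlated baseline drift within plates.
Passing tests therefore demonstrate the correctness and statistical
sanity of the pipeline under the stated distortion model — not
instrument-grade performance on real spectra, whose error levels
(e.g. test-set R² of 0.67–0.79 in comparable real screens) reflect
reference-method error and biological nuisance variation absent here.

## Numerical choices and degenerate inputs

Weighted least squares via `numpy.linalg.lstsq` on the √w-scaled design;
rank checked up front. PCA via SVD with a deterministic sign convention
(largest-magnitude loading element positive). Ties in factor selection
always resolve toward the smaller model. Samples flagged by EMSC (b ≈ 0)
are passed through uncorrected with a warning; zero-variance responses
are rejected at fit time and marked NaN in metrics. All randomness
(truth, noise, splits) flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams; region evaluation is a pure
function of (data, config, seed) and full runs are byte-reproducible.

Default problem sizes used by the test suite and the acceptance script —
the 312-spectrum default design, 5-seed FFA detection runs and 10-seed
region-ranking and cross-correlation sweeps — were chosen as the smallest
designs that exercise the full replicate hierarchy while keeping a
complete run in seconds on a laptop core.

## Known limitations

* PLS1 only (one response per model); no PLS2, no variable-selection
  algorithms beyond the fixed region presets, no uncertainty intervals
  on the regression vector.
* EMSC here is the classical polynomial variant; no Mie-scatter
  extensions, rubber-band or ALS baselines, or atmospheric correction.
* The band-intensity rule (windowed maximum with local offset) is
  deliberately simple; overlapping bands are not deconvolved.
* The calibration/test split stratifies by strain only; substrate
  balance within the test set is left to randomness.
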