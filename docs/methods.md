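# Methods

`qusrad` implements a complete desk-scale analysis chain for predicting
a binary breast-cancer recurrence-risk category (the Oncotype DX
recurrence score dichotomized at 15) from quantitative-ultrasound (QUS)
spectral parametric images: an RF phantom simulator with known
scattering ground truth, spectral parameter mapping, radiomics feature
engineering, a nested leave-one-out cross-validated (LOOCV)
classification protocol, and univariate screening statistics.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot show.

## 1. RF phantom simulator (`qusrad.phantom`)

**Model.**  The imaging plane is 2-D.  A phantom is a Poisson cloud of
point scatterers with areal density `scatterer_density_mm2` (default
80 /mm²).  Each scatterer takes the effective radius `a_eff` and the
acoustic concentration (AAC, dB) of the region containing it —
background, elliptical tumor core, or the 5 mm margin ring.  Amplitudes
are zero-mean Gaussian with variance `10^(AAC/10) / density`, so the
ensemble backscattered power tracks the linear concentration and
doubling the concentration raises the spectrum by 3 dB.  Margin
heterogeneity multiplies the amplitude s.d. by `exp(h/2 · g(x,z))`
where `g` is a smooth unit-variance random field (random-phase cosine
synthesis, correlation length 1.5 mm) and `h` is the class-effect dial.

**Echo formation** is linear and frequency-domain per lateral line:
each scatterer contributes a delayed replica of a Gaussian pulse
(center 6.5 MHz, two-way −6 dB band 3–8 MHz) shaped by the one-way
Gaussian form-factor response `exp(−b_ff k² a_eff²)` (`b_ff = 0.827`,
`k = 2πf/c`, `c = 1540 m/s`) and one-way attenuation `α·f·z` dB
(`α` in dB·cm⁻¹·MHz⁻¹, applied round trip as `2αfz`).  A separable
Gaussian lateral point-spread function (σ = 0.12 mm) couples
neighbouring lines so speckle is fully developed (≈ 8 scatterers per
resolution cell at the default density; envelope amplitudes pass a
Kolmogorov–Smirnov Rayleigh test).  White Gaussian noise is added at a
configurable SNR, 30 dB by default.

The backscatter model convention is `BSC(f) = C · f⁴ ·
exp(−2 b_ff k² a_eff²)` with the factor 2 arising from the squared
one-way response; simulator and estimator share this convention, so
ground-truth recovery is well defined.  The `f⁴` factor uses f in MHz;
absolute BSC units are arbitrary and cancel in reference-phantom
normalization.

**Cohort generator.**  Defaults mirror the study conditions: 10
low-risk and 21 intermediate-to-high-risk patients, 3 frames each
(frames per patient is not pinned down by the protocol; 3 is the
package default).  Tumor cores are ellipses with long axis drawn from a
lognormal matched to the printed size distribution (median 1.7 cm,
range 0.7–8.9 cm), truncated to the frame; the margin is the 5 mm
outward ring.  The class effect is placed where the discriminative
features live in the real data — margin texture: high-risk margins get
`margin_heterogeneity` 0.8 vs 0.1 and a +2 dB margin concentration
shift.  These effect sizes are a design choice that makes the
end-to-end pipeline detectably informative without claiming to
reproduce patient effect sizes.  The default frame is 26 × 30 mm
(fs 40 MHz axially, 0.12 mm lateral pitch) to keep a full cohort run
desk-scale; any FOV, including 4 × 6 cm, is a config change.

**What the phantoms do not emulate:** 3-D volumes and elevational
focusing, wavefront curvature and depth-dependent diffraction, real
tissue layering (skin is only an attenuation term in the correction),
system-dependent TGC, and biological covariance structure between
channels.  Passing tests therefore demonstrate correctness of the
estimators and the protocol under the stated scattering model, not
clinical performance.

## 2. QUS spectral mapping (`qusrad.spectral`)

A 2 × 2 mm window slides over core ∪ margin at 94% overlap, i.e. a
0.12 mm step (quantized to the sample/line pitch; the lateral pitch of
0.12 mm makes the lateral step exact, the axial step is 0.1155 mm).
Windows are tagged core/margin by their center point.

**Spectra.**  Per window, per line: Hann-gated FFT, squared magnitude;
powers are averaged across the window's 17 lines and — a variance
choice exposed as `n_axial_segments` (default 3) — across three
half-window Welch sub-segments.  The sub-segment averaging trades
axial spectral resolution (≈ 1.5 MHz main lobe against a 5 MHz band)
for a ≈ √3 reduction in per-window spectral noise; a single full-window
gate is `n_axial_segments=1`.

**Attenuation.**  Tumor attenuation is estimated once per frame by the
spectral-difference method: per frequency, mean dB power of the in-core
windows is regressed on depth; the per-frequency slope is `−2αf`
(round trip) and α follows from a zero-intercept fit of slope magnitude
against frequency (exact on closed-form input).  Correction adds
`Σ 2 α_layer f d_layer` dB per window using an assumed skin layer
(0.8 dB·cm⁻¹·MHz⁻¹ × 0.2 cm, both configurable — the predetermined
skin value is not published) plus the estimated tumor α over the
window's in-tumor path (depth below the ROI's top edge in its lateral
column).  Negative fitted α is flagged and clamped to 0 for correction.

**Parametrization.**  MBF/SS/SI come from ordinary least squares of the
corrected dB spectrum on frequency over 3–8 MHz; SS is the slope, SI
the 0 MHz value, and MBF the fit value at the *analysis-band midpoint*
(5.5 MHz) — "mid-band" is read as the analysis bandwidth, not the
transducer center frequency; the identity `MBF = SS·f_mid + SI` holds
to machine precision by construction.  The backscatter coefficient is
obtained by reference-phantom normalization
(`BSC = 10^((P_s−P_r)/10) · BSC_ref`) against a simulated homogeneous,
attenuation-free reference with known analytic BSC (the calibration
method is not published; the reference-phantom method is standard and
planar-reflector calibration is out of scope).  The Gaussian form
factor is inverted by linearizing `y = ln BSC − 4 ln f` against `f²`:
the slope gives `a_eff` (ASD = 2 a_eff), the intercept gives AAC in dB.
A non-negative slope (non-physical) yields ASD = 0, flagged, with AAC
from the f⁴-only fit.

**Accuracy at the default conditions** (30 dB SNR, ≥ 100 windows
averaged in linear power): recovered ASD within ~8% for ground truth
40–120 µm, AAC within 2 dB (the ASD = 120 µm case carries a ≈ 1.8 dB
systematic AAC bias from spectral leakage against the steep form-factor
decay), attenuation within ±0.01 of planted α ∈ {0, 0.7}.  Per-window
(map-pixel) estimates are noisier than window-averaged ones; on a
homogeneous phantom the per-channel spatial standard deviation is well
under 15% of each channel's display dynamic range, and the ASD map's
coefficient of variation is ≈ 10%.

## 3. Radiomics features (`qusrad.features`, `qusrad.texture`)

Per channel (MBF, SS, SI, ASD, AAC) and region (core, margin): z-score
× 100, drop |z| > 3 pixels, resample to an isotropic 0.12 mm grid
(cubic B-spline for the image, nearest neighbor for the mask), then a
single-level undecimated Coif1 wavelet decomposition (correlation with
the analysis filters, symmetric boundary extension) yielding LL/LH/HL/HH
subbands that keep the input shape so the ROI mask applies unchanged.
All image types share the fixed bin width of 15 for discretization
(`level = floor((x − min)/15) + 1`).

Features per image: 18 first-order statistics plus 75 texture features
— GLCM (24; 4 directions × distances 1–5, symmetric, feature-level
averaging over the 20 matrices), GLRLM (16; 4 directions, feature
averaging), GLSZM (16; 8-connected zones), NGTDM (5; distance-1
neighborhood), GLDM (14; distance 1, dependence tolerance 0).  Nine 2-D
shape features are computed once per patient from the core contour —
the only reading under which the total

    5 channels × 2 regions × (1 + 4 image types) × (18 + 75) + 9 = 4659

holds.  Degenerate regions take conventional values (GLCM correlation
and MCC = 1, skewness 0, Pearson kurtosis 3 on constants) so constant
patches yield defined features.  The implementation is an independent,
IBSI-consistent vectorized engine, cross-checked feature-by-feature
against a naive loop-based oracle in the test suite.  Per-frame vectors
are combined per patient by ROI-size (valid-pixel-count) weighted
averaging — a convex combination.

## 4. Nested LOOCV classification (`qusrad.pipeline`, `qusrad.metrics`)

The public surface is a Model/Results pair:
`RecurrenceModel.from_feature_matrix(df, classifier, config).fit()`
returns a `RecurrenceResults` with per-fold selections, aggregated
confusion counts, the metric panel with 95% intervals, per-feature
selection frequencies and a `summary()` table.

Per outer fold the development set (n − 1 patients) is processed in
this order: standardization (dev statistics only) → Isolation-Forest
outlier removal (⌈0.05 n⌉ most anomalous rows, skipped for a class it
would empty) → MRMR filter selection to `mrmr_k` features (relevance =
ANOVA F statistic, redundancy = mean |Pearson r| with the already
selected, greedy quotient with ε = 1e−12, index tie-break) → SMOTE
balancing for classifiers without class weighting (LDA, KNN; synthetic
points interpolated between minority nearest neighbors) or inverse
class-frequency weights (SVMs, random forest) → exhaustive
hyperparameter grid search in which every grid point is scored by
forward sequential feature selection (`sfs_k` features) under an inner
leave-one-out loop on balanced accuracy (ties: lower feature index;
grid ties: the earlier, simpler grid point).  SMOTE after MRMR avoids
synthesizing in 4659 dimensions.  The final model refits on the full
development set; the held-out patient receives a probability score
(logistic squash of the margin for SVMs), thresholded at 0.5.  The
left-out patient never touches any fitted statistic of its own fold —
asserted by a direct corruption experiment in the tests.

Metrics: the seven count metrics as percentages with Wald 95% intervals;
AUROC by trapezoidal ROC integration (equal to the tie-corrected
Mann–Whitney statistic to 1e−10) with a Hanley–McNeil interval; AUPRC
by right-step (average-precision) integration.  Undefined ratios (zero
denominators) are reported as NaN rather than imputed.  A
`complexity_sweep` repeats the whole nested protocol for 3–7 selected
features and reports the metric table plus selection frequencies.

Hyperparameter grids (the published table of grids is not available):
LDA {svd}; KNN k ∈ {3,5,7}; linear SVM C ∈ {0.1,1,10,100}; RBF SVM the
same C × γ ∈ {1/p, 0.01, 0.1}; RF {100, 300 trees} × depth {2, 3, ∅} —
modest grids sized to n = 31, all exposed in `ClassifierSpec`.
`reduced_classifier_specs()` trims these for permutation studies and
the desk-scale `run` default (MRMR pool 12).  Every stochastic stage
(forest, SMOTE, classifier) is seeded per fold from the config seed.

**Protocol calibration.**  On label-permuted synthetic cohorts (n = 31,
20 permutations) the aggregated balanced accuracy centers at chance
(measured 0.46 at seed 1), and a planted two-feature effect of 2.5 SD
yields SVM-RBF AUROC ≈ 0.97 — the leakage and power checks the
acceptance script recomputes.

## 5. Univariate screening (`qusrad.stats`)

Each MRMR-selected feature is tested between risk groups with a Welch
t-test when both groups pass Shapiro–Wilk normality at 0.05, otherwise
a two-sided Mann–Whitney U test (constant groups go to the rank test).
Flags are reported at raw 0.05 and at the Bonferroni level α/n_tests
(0.001 for the default pool of 50).  Sidedness (two-sided) and the
Welch variant are package choices; the family-wise error under a global
null is verified by simulation.

## 6. Reproducibility

All randomness flows from explicit integer seeds; identical seeds give
bit-identical cohorts, feature CSVs and confusion counts (asserted in
the tests).  `run_experiment` writes the fully-resolved config, a
manifest with per-stage wall clock and output SHA-256 checksums, and a
markdown report.  Problem sizes used by the test-suite and the
acceptance script — 20 × 20 mm phantoms with ≥ 20 000 analysis windows
for parameter recovery, 31-patient feature-level cohorts with a
reduced MRMR pool for the permutation null — are the package's
desk-scale defaults for these studies.

## Known limitations

- The simulator's 2-D plane understates the averaging a 3-D resolution
  cell provides; absolute per-window variances are not comparable to
  clinical systems.
- Welch sub-segmenting biases steep spectra slightly (the ASD 120 µm
  AAC bias above); set `n_axial_segments=1` for minimal-bias averaged
  estimates at the cost of noisier maps.
- Undecimated wavelet reconstruction via the adjoint is exact only away
  from image borders under symmetric extension; feature extraction uses
  only the analysis direction, so this affects nothing downstream.
- Wald intervals are anti-conservative at the extremes (a 10/10
  specificity reports 100 (100–100)); intervals are reported, never
  used for selection.
- With n = 31, nested LOOCV point estimates remain high-variance; the
  permutation null, not a single AUROC, is the meaningful calibration.
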