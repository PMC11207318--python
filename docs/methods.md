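# Methods

`hyperyield` studies how the spatial and spectral configuration of an
imaging system affects corn **silage** yield estimation from VNIR imaging
spectroscopy.  The campaign it emulates — a UAS-mounted 272-band
(400–1000 nm) line scanner at 0.063 m ground sample distance (GSD) over a
36-subplot nitrogen/manure trial — produced data that are not publicly
available, so every analysis here runs on a synthetic scene generator whose
structure mirrors that acquisition.  This note records the models, the
parameter choices, the numerical decisions, and what the synthetic results
do and do not establish.

## Pipeline overview

1. **Scene** — render a radiance cube with per-subplot canopy parameters,
   soil pixels, calibration panels, and sensor noise; link yields to canopy
   state (`synthetic_scene`).
2. **Calibration** — empirical line method (ELM): per-band affine
   radiance→reflectance map fit through the 6% and 55% Lambertian panels
   (`preprocess`).
3. **Band selection** — score every band by PCA-MV band power, LCMV-CBS
   constrained-filter error, and random-forest importance; convert score
   curves into (center, FWHM) band definitions with narrow/default/wide
   variants and two consensus configurations (`band_selection`).
4. **Virtual sensor** — build a spectral response matrix per configuration
   and integrate the *radiance* cube (and, by ELM linearity, the gain/bias
   vectors) into a multispectral product (`spectral_resample`).
5. **GSD degradation** — per subplot: tile eight copies, blur with a
   Gaussian PSF whose FWHM equals the target GSD, block-average to the
   target resolution (`spatial_resample`).
6. **Regression** — per-subplot mean spectra, one fixed 80/20 split, an
   RBF-kernel SVR tuned per dataset by leave-one-out CV, scored by MAPE (%)
   and RMSE (Mg/ha) (`yield_regression`, `experiment`).

## The synthetic scene

**Vegetation model.**  Reflectance is parametric, not radiative-transfer:
a logistic red-edge rise from a 0.05 visible baseline to a NIR plateau
(inflection 706–724 nm, slope 14 nm), a chlorophyll-scaled green peak
(Gaussian at 550 nm, amplitude 0.07·chl) and red absorption well (670 nm,
0.033·chl), and water-scaled dips at 820 and 940 nm.  Parametric spectra
make the features analytically checkable — the tests recover the red-edge
inflection from the derivative and the green/red contrast directly.  A
radiative-transfer canopy model (PROSPECT/SAIL class) would be more
faithful but is out of scope.

**Within-subplot variability.**  Each pixel perturbs its subplot's
chlorophyll and water levels along linearized spectral directions
(relative jitter 0.15), emulating leaf-to-leaf biochemical variation; an
optional multiplicative per-pixel speckle (brightness) term stands in for
leaf-angle/glint variability.  Soil pixels (slowly rising spectrum, red
reflectance above the vegetation green peak) are placed by seeded binomial
sampling at a 20% target share.

**Noise.**  Additive Gaussian radiance noise with a per-band sigma equal to
1% of the illumination scale, inflated ~3x below 450 nm and above 900 nm
(logistic shoulders), mirroring the blue/NIR noise of the emulated sensor.

**Yields.**  The canopy score is `1.0·chl + 4.0·nir_plateau` (chlorophyll
and canopy/biomass both drive silage mass, with the NIR weight dominant so
that yield-aware band selection sees the NIR plateau).  The score is
standardized against the sampling-range midpoint and passed through
`16·exp(0.8·z)` — a monotone, right-skewing link giving means near
16 Mg/ha (35% dry-matter convention) and sample skewness above +0.3 at
scale, matching the non-normal yield distributions such trials report.
Gaussian noise (sigma 0.25 Mg/ha) is added, with resampling of
non-positive draws.

**Problem sizes.**  A full-scale scene (36 plots of 238 × 968 px × 272
bands) would be ~10 GB; all packaged runs use scaled scenes.  Defaults:
272 bands, 36 subplots of 64 × 240 px at 0.063 m (4 × 15 m mini-plots,
aspect as in the trial); tests and the trend study use a 61-band, 10 nm
variant with 32 × 120 px or 16 × 60 px subplots.  Subplot pixel extents are
chosen divisible by the block sizes of the degradation ladder so block
averaging needs no cropping at the key rungs.

## Calibration (ELM)

Per band, `gain = (0.55 − 0.06)/(L_light − L_dark)` and
`bias = 0.06 − gain·L_dark`, with panel radiances taken as mask means
(median optional).  The map is affine, hence exactly invertible per band
and exact on the panel means by construction.  The equidistance assumption
behind using one line for the whole swath is checked geometrically: at
100 m altitude and a 15 m swath the edge pixel is
`sqrt(100² + 7.5²) − 100 = 0.281 m` farther (0.281% < 0.3%).  The
closed form is reported as computed, without chasing printed roundings.

## Denoising

BayesShrink soft-threshold wavelet smoothing runs 1-D along each pixel's
spectrum (no spatial mixing): `sym4` wavelet, decomposition level
`floor(log2 n) − 2`, per-pixel noise sigma from the MAD of the finest
detail coefficients divided by 0.6745, per-level threshold
`sigma_n²/sigma_x`.  Constant and already-smooth spectra pass through
unchanged (idempotence to ~1e−8); a narrow injected absorption dip at
762 nm is damped but not removed, the expected behaviour for a feature a
few bands wide.  A Fourier/PSD filter variant is deliberately not offered.

## Band selection

**PCA-MV.**  The pooled pixel matrix's *uncentered* second-moment matrix is
eigendecomposed and band *l* scored by
`rho_l = sum_n lambda_n V[n,l]² / sum_m lambda_m`.  The narrative of the
source method reads "multiplied by their corresponding eigenvectors"; this
implementation reads *eigenvalues* — with an orthonormal eigenbasis and no
eigenvalue weighting the score is identically 1.  With every component
retained, `rho = diag(Sigma)/trace(Sigma)` exactly; this closed form is the
test oracle, and a component-truncation option (which breaks the
equivalence) is provided.  Mean-centering is a flag, off by default.

**LCMV-CBS.**  Each band image `b_l` (all pixels as one vector) gets the
minimum-output-energy filter under `b_lᵀ v_l = 1` against
`R = (1/L) Σ_l b_l b_lᵀ + delta·I`, and the score is
`tau_l = 1/(b_lᵀ R⁻¹ b_l)`.  Two numerical points: (i) `R` is P × P but
rank ≤ L, so everything is computed through the Woodbury identity on the
L × L band Gram matrix — `R` is never formed; (ii) in the
vanishing-ridge limit the score degenerates to the flat pseudo-inverse
value 1/L for *every* band, so a meaningful ridge is essential.  The ridge
is `delta = epsilon · trace(R)/P`; scoring runs use `epsilon = 10` (about
ten times the mean diagonal), while the oracle tests use small epsilon and
verify `tau` against a numerically solved constrained quadratic program to
1e−6.

**RF importance.**  A 500-tree random-forest regression of yield on
subplot mean spectra; impurity importances normalized to sum 1, fixed
seed.  This is the only score that sees yield.

**Score → bands.**  Curves are smoothed (5-band moving average; RF curves,
which scatter split credit across adjacent correlated bands, get a ~45 nm
window), thresholded at `median + 2·MAD`, and local maxima above the floor
become band centres with FWHM = width at half prominence (≥ 2 grid
spacings).  Adjacent centres must be separated by at least the larger of
the two FWHMs (so each band integrates mostly unique spectrum); the
lower-scoring band of a violating pair is dropped.  Width variants scale
every FWHM by 0.5 (narrow) or 1.5 (wide) and re-apply the rule.

**The canonical 11-configuration suite.**  The campaign tabulated only its
RF-derived sensor (432/512/592/686/766/844/929 nm with 30/30/30/20/30/20/10
nm bandwidths); its PCA-MV and LCMV-CBS configurations were never printed.
The packaged suite therefore combines that tabulated seven-band
configuration with two *synthetic stand-ins*: LCMV from its five reported
default/narrow overlap centres (500, 615, 670, 775, 840 nm; nominal
20–30 nm widths) and PCA as a seven-band sampling of the vegetation
spectral features its score curve mirrors (445–875 nm; the 785/875 nm NIR
peaks also emerge from this package's own PCA scores on synthetic scenes).
Three defaults × three width variants + two consensus configurations
(centres shared by ≥ 2 methods within 10 nm, clustered greedily; the second
adds the 715 nm / 30 nm red-edge band) = 11, matching the campaign's count
and giving the 110-dataset cross-product with the ten-GSD ladder.  A fully
procedural `build_config_suite` derives all 11 from a scene at run time;
it is exercised in the tests but, with only 36 subplots, its RF peak
positions are seed-dependent, which is why the canonical suite is frozen.

## Spectral resampling

Gaussian SRF rows use **sigma = FWHM** — the emulated chain's stated
(unconventional) choice — truncated at 3 sigma and renormalized to unit
sum; `sigma_convention="conventional"` gives sigma = FWHM/2.355.  A
rectangular SRF (uniform over ± FWHM/2) is provided for comparison.
Integration happens in radiance; the ELM gain/bias vectors are integrated
through the same rows, and the resampled product is converted with the
resampled coefficients.  For non-flat gains the two orders of operations
differ by `W(g∘L) − (Wg)(WL)`; the tests compute that discrepancy both
ways and the pipeline accepts it, as the emulated chain does.

## Spatial degradation

Per subplot: tile (eight copies in a 2 × 4 grid, raising 0.09 ha to
0.72 ha so even a 30 m pixel sees data), blur each band with a Gaussian
PSF of FWHM (in metres) = target GSD (unit-sum kernel, size 3 sigma), then
non-overlapping block means with edge `round(target/native)` px; the
*realized* GSD is recorded rather than forcing the nominal value.

**Boundary handling (a deliberate design choice).**  Tiling is periodic
replication, so the package's default blur boundary is periodic (`wrap`):
the blurred mosaic remains exactly periodic and every band mean is
conserved exactly, with large-sigma blurs running through the FFT (exact
for circular convolution).  The alternative zero-pad treatment
(`boundary="zero"`) pads by the PSF half-width and records the
boundary-influenced ring (pad + blur reach) in metadata; means then
exclude that ring and are conserved only approximately (~1e−3 relative),
because the clean interior is a sub-period sample of the mosaic.  Both
modes are tested; the experiment grid uses `wrap`.

## Regression

Features are per-subplot arithmetic mean spectra (pad-ring excluded for
zero-boundary products).  One seeded 80/20 split (36 → 29 train / 7 test,
floor on the test share) is created once and reused for every dataset.
Per dataset, features are z-scored with training statistics (zero-variance
bands dropped with a warning) and an RBF SVR is tuned over
C ∈ {10¹…10⁵} × gamma ∈ {10⁻⁵…10⁻¹} (log-decade steps, epsilon = 0.1) by
leave-one-out CV scored with MAPE; ties resolve toward smaller C, then
larger gamma.  LOO has no randomness, so the whole procedure is
deterministic.  MAPE is implemented with absolute values and reported in
percent (the printed source formula omits both, but its name and quoted
results imply them); RMSE is reported in Mg/ha.

## The experiment grid and the resolution trend

`run_grid` crosses configurations with GSDs, records every cell (failures
as error tokens, never silent gaps), and reports MAPE and RMSE tables with
per-metric best cells — the two rankings need not agree.  The full-size
ladder is {0.063, 0.13, 0.25, 0.5, 0.76, 2.02, 4.03, 8.06, 16.32, 30} m;
demonstration runs on the mini-plot scene use a ten-rung ladder capped at
8.06 m (block edge 128 px = the tiled mini-plot height), with 1.008 and
3.024 m (16x and 48x native) filling the last two rungs.

**What the trend study shows — and what it cannot.**  Because every stage
of the cascade is linear and the features are subplot means, mean
conservation makes the feature vectors *identical* across GSDs up to
rounding: pixel-scale speckle commutes with the mean, so spatial
pre-averaging cannot change a mean-spectrum feature.  The packaged trend
study (ten speckled scene seeds, native 0.25 m vs. 2.02 m, the seven-band
sensor, double precision) therefore verifies that the coarse product is
*no worse* than native — the medians tie to ~1e−11, and the test allows
0.001 percentage points for floating-point noise.  A genuine accuracy
*peak* at 2–8 m of the kind reported on real data would require effects
this generator does not model (shadowing, leaf-angle variance, canopy
texture interacting nonlinearly with the sensor); establishing it
synthetically would need a structurally richer scene, not a parameter
change.

## Known limitations

- Parametric spectra, no BRDF, no temporal dimension, no georeferencing.
- The PCA/LCMV members of the canonical suite are labelled synthetic
  stand-ins, not recovered campaign configurations.
- Accuracy figures from synthetic scenes (typical grid MAPE ~2–7%,
  RMSE ~0.3–1.4 Mg/ha at demonstration scale) characterize the pipeline on
  this generator only; they are not estimates of real-field performance.
- The yield link and its noise are the generator's choice; only its
  qualitative properties (monotonicity, right skew, positivity) are
  asserted.
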