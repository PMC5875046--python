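# Methods

This note documents the models, estimators and numerical choices behind
`ctiq`, in the spirit of a methods appendix: what is simulated, what is
measured, which knobs matter, and what the validation does and does not
show.

## Phantom scenes and rasterization

A phantom slice is a declarative scene (`PhantomLayout`): an elliptical body
(optionally inside a fat-equivalent ring ellipse, −90 HU) holding labelled
primitives — disks (cylinder inserts in cross-section), annuli, and
resolution bar groups — each with a nominal HU in [−1000, 3000]. Built-in
layouts model the three Catphan-600-style modules at their true scales
(eight 12.2 mm sensitometry inserts on a 58.4 mm radius circle in a +100 HU
background; a 15 mm supraslice target at +10 HU contrast — the conventional
reading of "1%" contrast, configurable; bar groups from 1 to 8 lp/cm at
1000 HU) and a simplified abdomen (soft-tissue ellipse with liver, spleen,
pancreas and kidney disks). Geometry is in millimetres relative to the
phantom centre; pixel centres are at (i + 0.5)·Δ from the image corner with
Δ = DFOV·10/matrix (0.703125 mm at the default 36 cm / 512).

Rasterization classifies pixels by their centre and supersamples a
two-pixel morphological band around every boundary (16 × 16 sub-pixel
points), giving area-weighted anti-aliased edges: a disk's summed coverage
matches πr² to well under 0.5%, and interior pixels equal the nominal HU
exactly. Small primitives (bar groups near the Nyquist frequency) are
supersampled over their whole bounding box since a thin bar can vanish from
a centre-sampled mask.

## The reconstruction-algorithm emulation

Actual tomographic reconstruction is out of scope; FBP, the ASiR blends and
MBIR are emulated in the image domain by an `AlgorithmModel` with three
laws, all overridable:

- **Noise magnitude.** σ(dose) = factor(dose) · σ_ref · (dose_ref/dose)^e ⊕
  floor, combined in quadrature. e = 0.5 is the quantum-statistics default;
  the additive electronic floor captures low-dose departures from pure
  √dose scaling and defaults to 0 so that the calibration below holds
  exactly. `noise_sigma_model` exposes the closed form for truth-vs-measured
  tests. Dose-dependent factors are piecewise-linear in log-dose, clamped at
  their endpoints.
- **Resolution.** An effective *total* Gaussian system PSF σ_psf(dose).
  FBP/ASiR are dose-insensitive (0.80 / 0.79 / 0.78 / 0.75 mm for
  FBP / 20% / 40% / 70%); MBIR improves with dose, 0.78 mm at 1 mGy to
  0.50 mm at 24 mGy, linear in log-dose. These defaults make the MBIR/FBP
  MTF ratio at 5 lp/cm rise from ≈1 at 1 mGy to ≈7 at 24 mGy, the
  qualitative behaviour reported for model-based reconstruction.
- **HU bias.** FBP and the ASiR blends are unbiased (enforced for FBP).
  MBIR reads 10 HU low for soft materials, scaled by |HU|/400 above 400 HU
  (dense materials deviate more), and grows by 30% per log-dose unit below
  3 mGy (low-dose HU instability).

Default noise calibration: FBP σ_ref = 66.7 HU at 1 mGy (log-noise ≈ 4.2);
ASiR factors 0.85/0.75/0.60; MBIR factor 0.20 at ≤3 mGy rising to 0.50 at
24 mGy — i.e. five-fold below FBP at low dose. Pitch is metadata by
default; optional per-pitch noise/PSF multiplier tables reproduce
pitch-dependent effects when wanted.

**Simulation of a replicate stack.** Each replicate is the rendered scene
with the per-material HU bias applied, blurred to the total system PSF,
plus zero-mean noise of exactly σ(condition) per pixel. Two numerical
choices matter:

1. *Band-limiting before sampling.* The scene is rendered on a 4× finer
   grid, blurred there, and box-averaged down. The fine-grid area-weighted
   render followed by the r×r block average composes to exactly the coarse
   pixel-box aperture, whose variance w²/12 is subtracted from σ_psf² for
   the applied Gaussian — so the end-to-end edge response is Gaussian with
   the requested σ (residual, the sinc-vs-Gaussian fourth-order mismatch,
   < 0.5% where MTF ≥ 0.1). Blurring directly on the target grid would
   alias the sharp-edge spectrum and corrupt the measured MTF by several
   percent. When σ_psf is below the pixel-box width the plain render is
   used unchanged (degenerate, effectively unblurred case).
2. *Noise.* White Gaussian by default. The per-pixel σ is exact; a
   Gaussian-correlated texture (configurable correlation length, rescaled
   to preserve per-pixel σ) is available but off by default, because
   correlation biases the sample SD inside small ROIs low (≈6% for
   0.4 cm² ROIs at 0.6 mm correlation) and the validation suite is defined
   against the closed-form σ. Real CT noise *is* textured; measurements on
   real data inherit that bias and the tests here do not speak to it.

Replicate k draws from the counter-based substream (seed, k), so a stack is
bit-reproducible and any single replicate can be regenerated alone.

## ROI metrics

A pixel belongs to a circular ROI iff its centre lies inside; sample SDs
use n−1. ROIs with fewer than 10 pixels are rejected as unstable. Noise is
the mean of the per-ROI SDs (three 0.4 cm² background ROIs at 120°
spacing), averaged over replicates. CNR pools the three background ROIs'
pixels for the background mean and SD (pooling is the more stable choice;
the per-ROI-average variant is available via `pool_background=False` since
the original description does not disambiguate). Insert HU uses ROIs at 70%
of the insert radius, pooled across replicates. Fold-improvement ratios are
oriented so that >1 always means better than the reference algorithm
(reference/value for noise, value/reference for CNR).

## Edge-method MTF

Profiles start at the centre of the circular air target (14 mm, two
horizontal and two diagonal at 45°/225°; the diagonal angles are a choice —
only "diagonal" is specified) and are sampled by bilinear interpolation at
half-pixel steps. ESF → LSF by central differences (one-sided at the ends);
the mean of the last 10% of LSF samples (far-field tail) is subtracted; no
apodization. Spectra are zero-padded ≥4×, and the magnitude spectra of all
profiles and replicates are **summed first and normalized once** at zero
frequency (sum-then-normalize, matching the source method; the suite
regression-tests this against the normalize-then-average alternative).

At CT pixel sizes this raw chain attenuates the spectrum by tens of percent
at the frequencies of interest, so the known transfer factors are divided
out per profile before summation:

- the central difference over step h is exactly a moving average of the
  true LSF over 2h — factor sinc(2fh);
- bilinear interpolation at each sample's fractional pixel offset has a
  closed-form per-axis transfer; the per-profile mean is used;
- when the edge-target radius is supplied, a second pass replaces both with
  an *exact chain reference*: the closed-form edge profile of a
  Gaussian-blurred disk (a noncentral-χ² CDF) is evaluated through the
  identical sampling/derivative/FFT chain using each profile's actual
  bilinear weights, and the measured spectrum is divided by
  (reference chain)/(target Gaussian). This also removes the ≈2%
  edge-curvature bias of the 6.1 mm target. The reference blur is the
  Gaussian σ fitted to the first-pass curve (median over mid-modulation
  bins) — the correction varies only second-order in that estimate, and it
  assumes an approximately Gaussian MTF, which holds for this generator.

Summing magnitudes puts a positive Rician floor under the curve wherever
noise competes with signal. Replicate profiles of one orientation share the
identical noiseless signal, so the spread of their complex spectra
estimates the per-bin noise SD; the exact Rice mean is then inverted to
debias the summed magnitude. Consequences worth knowing: (a) a modulation
genuinely below the noise floor debiases to ~0 rather than to a spurious
positive value (FBP at 5 lp/cm under 24 mGy noise is in this regime, which
is also why scanner studies report very wide MTF-ratio CIs there); (b) on
real data any replicate-to-replicate signal change (drift, misregistration)
would inflate the noise estimate — the generator has none.

Validation: noiseless, the aggregated curve tracks exp(−2π²σ²f²) within
0.5% wherever the analytic value ≥ 0.1; with 10 replicates at the default
MBIR high-dose noise (σ ≈ 6.8 HU) the remaining deviation is sampling
scatter of order 2–4% at the lowest masked modulations (the information
limit of 40 magnitude spectra at that SNR — per-profile SNR ≈ 2.7 at the
MTF = 0.1 point).

Bar-pattern modulation is (mean per-period peak − mean trough) / nominal
plateau contrast along a profile through the bar group, validated against a
brute-force 1-D square-wave convolution oracle.

## Statistics

With balanced single-level replication the "mixed model" reduces to closed
form, which is what is implemented: per-condition means of (log-)values
with t-based 95% CIs. Noise and MTF are analysed on the natural-log scale
(multiplicative dose scaling, skewness reduction); CNR raw. Contrasts
against the reference condition use the variance pooled across all
conditions on the analysis scale (homoscedastic residuals on the log scale,
the classic balanced many-to-one design), giving equicorrelated contrasts
with ρ = 1/2 and t statistics that share one denominator — exactly the
multivariate-t null that Dunnett's single-step procedure assumes. When only
published summary rows (mean + CI, no replicates) are supplied, standard
errors are backed out of the CIs and combined per contrast (Welch); the
point differences are exact either way, but the resulting CIs need not
match a mixed model's, whose covariance structure is not recoverable from
the summaries.

`dunnett_adjust` computes two-sided adjusted p = P(max_j |T_j| ≥ |t|) for k
equicorrelated t variates by deterministic quadrature (120-node
Gauss–Hermite over the shared normal factor × adaptive quadrature over the
χ_ν scale; k = 1 short-circuits to the exact unadjusted p). A seeded
max-|T| Monte-Carlo mode exists as an independent check; the suite verifies
the quadrature against a 10⁷-draw simulation (|Δ| < 10⁻⁴), against
`scipy.stats.dunnett` on sampled data, against the Šidák bound at ρ = 0,
and confirms 5% family-wise error on 500 null pipeline runs.

MTF ratio tables exponentiate mean log-MTF differences (algorithm −
reference) per pitch × dose cell with pooled within-cell variance, Dunnett
adjustment across the cell's contrasts, and back-transformed CIs; the ratio
equals the ratio of geometric means identically.

## Pipeline, sizes and determinism

`run_experiment` walks the condition grid; per-condition seeds derive from
the master seed by counter-based `SeedSequence` keys, so outputs are
byte-identical under a fixed seed (checksummed manifest; `verify_manifest`
detects corruption). Default problem sizes follow the study design: 512²
images at 36 cm DFOV, 10 replicates, doses 1–24 mGy. The validation suite
and the acceptance script scale some stages down or up deliberately: the
type-I-control runs use a 128² uniform phantom (the statistic only needs
three background ROIs), and the CNR fold-improvement cell uses 160
replicates because |ΔHU| = 10 against σ = 66 HU noise makes the per-replicate
CNR extremely scattered at 1 mGy (the |·| folding also biases the FBP CNR
slightly upward, which is why the recovered CNR fold sits near 4.8–5.2
rather than exactly at the 5.0 noise-factor design value). Stacks persist
as int16 rasters + JSON sidecar (lossless for integer HU) or as DICOM CT
slices with RescaleSlope/Intercept honoured on read.

## Known limitations

- Image-domain emulation only: no projection physics, beam hardening,
  helical cone-beam effects, or nonstationary/nonlinear iterative
  reconstruction behaviour (real MBIR violates the shift-invariance the
  FFT-based MTF assumes; the emulation is, by construction, linear).
- White noise default; no noise-power-spectrum shaping or validation.
- The abdomen phantom is geometric (ellipse + organ disks), not anatomical.
- ROI geometry is declarative; there is no registration or landmark
  detection for real scanner images.
- The MTF chain corrections assume the profile geometry is known exactly
  and (for the second pass) an approximately Gaussian MTF; both hold for
  the generator but only approximately for real scanners.
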