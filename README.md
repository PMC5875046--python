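# ctiq — synthetic CT phantom simulation and image-quality analysis

`ctiq` is a Python library for the quantitative image-quality workflow used
to evaluate CT iterative-reconstruction algorithms for dose reduction:
ROI-based noise and contrast-to-noise ratio (CNR), insert Hounsfield-unit
(HU) accuracy, the edge-method modulation transfer function (MTF), and
Dunnett-adjusted statistical comparison across reconstruction algorithm ×
dose × pitch grids. Because scanner acquisitions of a physical phantom are
not reproducible on a desk, the package pairs every analysis stage with a
**synthetic phantom-image generator with known ground truth** — a
Catphan-600-style sensitometry / low-contrast / bar-pattern phantom wrapped
in a fat-equivalent ring, plus a simplified anthropomorphic abdomen — so
each measurement can be validated against the truth that generated it.

It is aimed at medical physicists and imaging scientists who want a tested,
scriptable reimplementation of this analysis (e.g. to prototype protocols,
teach QA metrics, or benchmark measurement code), not at clinical QA of real
scanners.

## The metrics

For replicate slice images in HU with pixel spacing Δ (DFOV/512):

- **Noise** — the mean of the sample standard deviations of three 0.4 cm²
  circular ROIs in the phantom's background material, averaged over 10
  replicate acquisitions.
- **CNR** — `|object HU − background HU| / background SD`, with identically
  sized ROIs on a 15 mm low-contrast supraslice target (+10 HU) and its
  immediate background.
- **Edge-method MTF** — 14 mm line profiles starting at the centre of the
  circular air insert (two horizontal, two diagonal) give the edge-spread
  function ESF(r); the line-spread function is LSF = dESF/dr by central
  differences; MTF(f) = |FFT(LSF)| normalized to f = 0. Magnitude spectra of
  all 4 profiles × 10 replicates are summed before the single normalization.
  The implementation divides out the known transfer of the numerical chain
  (finite-difference aperture, bilinear interpolation, edge curvature) and
  removes the Rician noise floor inherent to magnitude summation.
- **HU accuracy** — per-insert mean ± SD (air −1000, PMP −200, LDPE −100,
  water 0, polystyrene −35, acrylic 120, Delrin 340, Teflon 990), and deltas
  from the FBP / 24 mGy reference.
- **Statistics** — noise and MTF are analysed on the natural-log scale;
  per-condition means carry t-based 95% CIs; every condition is contrasted
  against a baseline (MBIR at 1 mGy for noise/CNR, FBP per cell for MTF
  ratios) with Dunnett's single-step multiplicity adjustment under the
  equicorrelated multivariate-t null (deterministic quadrature).

The generator emulates reconstruction algorithms in the image domain:
σ(dose) = noise_factor(dose) · σ_ref · (dose_ref/dose)^½ ⊕ electronic floor
(quadrature), an effective Gaussian system PSF (dose-dependent for MBIR),
and an HU-bias law (MBIR reads ≈10 HU low, more for dense materials and at
very low dose). Default calibration puts FBP log-noise at 1 mGy near 4.2
(≈67 HU) and MBIR five-fold below FBP at low dose.

## Worked example

```python
from ctiq import builtin_layouts, builtin_models, noise_sigma_model, simulate_stack
from ctiq.pipeline import CATPHAN_NOISE_ROIS
from ctiq.roi import measure_noise
from ctiq.simulate import ScanCondition

layout = builtin_layouts("ctp404")
model = builtin_models()["FBP"]
condition = ScanCondition("FBP", ctdi_vol=3.0, pitch=0.984)
stack = simulate_stack(layout, condition, model, n_replicates=5, seed=42)
print(noise_sigma_model(model, condition), measure_noise(stack, list(CATPHAN_NOISE_ROIS)).summary)
```

Running `python examples/01_render_and_simulate.py` (which wraps the above)
prints:

```
simulated 5 replicates of FBP@3mGy/p0.984, 512x512 px at 0.7031 mm/px
noise law sigma = 38.51 HU; measured (mean of 3 ROI SDs) = 38.71 HU
```

i.e. the ROI noise statistic recovers the generator's closed-form noise law
(38.5 HU for FBP at 3 mGy) within chi sampling error, and the insert HU
means printed below it sit at their nominal values. The other scripts in
`examples/` walk through the dose–response and fold-improvement tables
(`02`), the edge-method MTF of FBP vs MBIR (`03`), and the
Dunnett-adjusted comparison table built from the published per-condition
summaries bundled with the package (`04`).

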