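"""Edge-method MTF from the air insert: FBP vs MBIR at high dose.

Measures the modulation transfer function from 14 mm line profiles across
the circular air target (two horizontal, two diagonal, 10 replicates,
magnitude spectra summed then normalized) and compares the two algorithms
at 5 lp/cm. MBIR's narrower high-dose PSF shows up as a higher MTF.
"""

from ctiq import builtin_layouts, builtin_models, simulate_stack
from ctiq.mtf import aggregate_mtf, extract_edge_profiles, mtf_at_frequency
from ctiq.simulate import ScanCondition

layout = builtin_layouts("ctp404")
air = layout.feature("air")
models = builtin_models()

for name in ("FBP", "MBIR"):
    cond = ScanCondition(name, 24.0)
    stack = simulate_stack(layout, cond, models[name], n_replicates=10, seed=3)
    sets = [
        extract_edge_profiles(stack.images[k], stack.pixel_spacing_mm, air.center,
                              replicate=k)
        for k in range(stack.n_replicates)
    ]
    curve = aggregate_mtf(sets, spacing_mm=stack.pixel_spacing_mm,
                          edge_radius_mm=air.radius)
    m3 = mtf_at_frequency(curve, 3.0)
    m5 = mtf_at_frequency(curve, 5.0)
    print(f"{name}: PSF sigma {models[name].psf_sigma(24.0):.2f} mm -> "
          f"MTF(3 lp/cm) = {m3:.3f}, MTF(5 lp/cm) = {m5:.3f} "
          f"({curve.n_profiles_aggregated} profiles aggregated)")
# MBIR's dose-dependent PSF (0.50 mm at 24 mGy vs 0.80 mm for FBP) transfers
# much more contrast at mid frequencies. At 5 lp/cm FBP's true modulation
# (~0.04) sits below this measurement's noise floor, so after noise-floor
# removal it reads as ~0 - the same regime in which scanner studies report
# very wide MTF-ratio confidence intervals at that frequency.
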