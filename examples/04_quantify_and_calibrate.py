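"""Scanometric quantification against a dose-response curve.

Fits a four-parameter logistic to a synthetic calibration table, then
renders an assay at a known analyte concentration, measures the test
lines' ODR and inverts the curve to recover the concentration.
"""

import numpy as np

from barcodeassay import (
    AssayLayout,
    RenderScenario,
    SamplingPlan,
    assay_regions,
    background_region,
    estimate_concentration,
    fit_calibration,
    make_synthetic_calibration,
    measure_assay,
    qualitative_call,
    render_assay,
)

# 1. calibration: blank ODR ~0.04, saturation ~0.55 near 15 units
table = make_synthetic_calibration(n=8, noise_sd=0.02, seed=42)
curve = fit_calibration(table)
print("fitted 4PL: lower=%.3f upper=%.3f midpoint=%.2f slope=%.2f"
      % (curve.lower, curve.upper, curve.midpoint, curve.slope))
print("quantifiable range: %.2f - %.1f %s"
      % (*curve.valid_range, curve.concentration_unit))

# 2. a specimen at 4.0 mIU/mL: its ODR follows the true curve
true_conc = 4.0
specimen_odr = float(curve.predict(true_conc))
layout = AssayLayout()
scen = RenderScenario(
    strip_odrs={1: specimen_odr, 2: 0.8, 3: specimen_odr, 4: 0.8},
    noise_sigma=1.5, seed=7,
)
img = render_assay("-", layout, scen)

# 3. measure the strip interiors and call the test
strips = assay_regions("-", layout, inset_mm=2 * scen.blur_sigma)
plan = SamplingPlan(pixels_per_group=min(
    4715, min(r.width * r.height for r in strips) // 3))
measured = measure_assay(img, strips, background_region("-", layout), plan)
call = qualitative_call(measured)
test_odr = float(np.mean([m.odr for m in measured
                          if m.strip_index % 2 == 1]))  # strips 1 and 3
print(f"\nqualitative call: {call.result}")
print(f"test-line ODR: measured {test_odr:.3f} (target {specimen_odr:.3f})")

# 4. invert the curve
est = estimate_concentration(test_odr, curve)
print(f"estimated concentration: {est.value:.2f} {est.unit} "
      f"(interval {est.interval[0]:.2f}-{est.interval[1]:.2f}; "
      f"true {true_conc:.2f})")
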