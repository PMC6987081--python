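# rbc-oxyshear

From red-blood-cell deformability measurements to elongation-index maps in a
blood vessel, under oxygenated and deoxygenated conditions.

Red blood cells (RBCs) stretch under the shear stresses of flowing blood, and
how much they stretch depends on the oxygen saturation of their hemoglobin:
deoxygenation measurably *increases* shear-induced deformability.  An
ektacytometer (LORRCA-type Couette device) quantifies this as the elongation
index of the laser-diffraction pattern of sheared cells,

    EI = (a - b) / (a + b),

measured at a ladder of ten shear stresses from 0.3 to 50 Pa.  This package
implements the full desk-scale computational chain that turns such
measurements into spatial elongation maps:

1. **Ektacytometry** — EI from diffraction axes; deformability-curve
   parameterization by the Lineweaver–Burke linearization of the saturating
   hyperbola (EI_max, SS_1/2, SS_1/2/EI_max).
2. **Calibration** — nonlinear least-squares fit of the two-term exponential
   bridge EI(SS) = c1·e^(r1·SS) − c2·e^(−r2·SS), with built-in published
   coefficient presets for oxygenated (0.5464, 0.00356, 0.5224, 0.5395) and
   deoxygenated (0.5483, 0.003966, 0.5006, 0.598) whole blood, plus
   evaluation, inversion and R².
3. **Rheology** — the Casson yield-stress shear-thinning law
   μ(γ̇) = (√(τ_y/γ̇) + √μ_c)², hematocrit-dependent, with the nominal
   0.0035 Pa·s fallback at vanishing shear rate.
4. **Flow** — fully developed steady and pulsatile (sinusoidal, 0.1–0.5 m/s,
   0.5 s period) laminar flow of the Casson fluid in straight channels and
   tubes, verified against a semi-analytic Casson–Poiseuille oracle; wall
   shear stress extraction; VTK field export.
5. **EI mapping** — shear-stress fields pushed through a calibration into
   elongation-index fields; wall-vs-center contrast and
   oxygenated/deoxygenated comparison.
6. **Synthetic data** — a LORRCA-like generator (10 subjects × 2 replicates ×
   2 conditions × 2 phases) with known ground truth for recovery tests.

The regression-shaped pieces (`LineweaverBurkeRegression`,
`TwoTermExponentialCalibration`) are scikit-learn style estimators with
`fit`/`predict` and trailing-underscore attributes.

## Worked example

```python
import numpy as np
from rbc_oxyshear import (
    SynthConfig, generate_dataset, fit_calibration, lineweaver_burke_fit,
    get_preset, FlowProblem, solve_steady, map_ei, compare_conditions,
    wall_center_ratio,
)
from rbc_oxyshear.pipeline import mean_curve

curves = generate_dataset(SynthConfig(seed=17))            # 80 synthetic curves
oxy_mean = mean_curve(curves, "oxygenated", "before_5Pa")
cal = fit_calibration(oxy_mean, seed=17)
lb = lineweaver_burke_fit(oxy_mean)
print(f"fitted EI(SS) = {cal.c1:.4f} exp({cal.r1:.5f} SS) - {cal.c2:.4f} exp(-{cal.r2:.4f} SS)")
print(f"R^2 = {cal.r_squared:.4f};  EI_max = {lb.ei_max:.3f}, SS_1/2 = {lb.ss_half:.3f} Pa")

field = solve_steady(FlowProblem(inlet=0.3))               # steady channel, Casson blood
ei_oxy = map_ei(field, get_preset("eq1_oxygenated"))
ei_deoxy = map_ei(field, get_preset("eq2_deoxygenated"))
cmp = compare_conditions(ei_oxy, ei_deoxy)
print(f"oxygenated EI field: [{cmp['oxy_min']:.3f}, {cmp['oxy_max']:.3f}]")
print(f"deoxygenated higher in {cmp['fraction_deoxy_higher']:.0%} of cells")
print(f"wall/center EI ratio (steady): {wall_center_ratio(ei_oxy):.2f}")
```

prints

```
fitted EI(SS) = 0.5429 exp(0.00350 SS) - 0.5228 exp(-0.5367 SS)
R^2 = 1.0000;  EI_max = 0.669, SS_1/2 = 1.770 Pa
oxygenated EI field: [0.024, 0.253]
deoxygenated higher in 100% of cells
wall/center EI ratio (steady): 6.17
```

The fitted coefficients recover the oxygenated preset the generator was built
from (noise σ = 0.005 averages out over 10 subjects × 2 replicates); the EI
floor 0.024 is the calibration's zero-stress value (cells at the centerline,
where the stress falls below the measurable range); cells near the wall are
several times more elongated than cells at the center, and deoxygenated blood
elongates more everywhere.  Under the default pulsatile inlet the per-phase
wall/center ratio varies through the cycle and reaches the 5–10× range
(`wall_center_ratios` over `solve_pulsatile(FlowProblem()).fields`).

## Command line

```sh
rbc-oxyshear synth --seed 42 --out curves.csv
rbc-oxyshear lb-fit curves.csv --out params.csv
rbc-oxyshear calibrate curves.csv --condition oxygenated --seed 17 --out cal.json
rbc-oxyshear simulate --config flow.yaml --out fields/     # VTK legacy output
rbc-oxyshear map-ei --config flow.yaml --out ei/
rbc-oxyshear run --config run.yaml --out report.json
rbc-oxyshear report report.json
```

Configuration files are YAML; see `docs/methods.md` for the keys and the
model/solver details.

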