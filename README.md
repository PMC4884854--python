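# nlswei — nonlinear shear-wave elastography simulation

`nlswei` simulates **compression-enhanced shear-wave elasticity imaging
(SWEI)** on a two-dimensional hyperelastic breast phantom.  Shear-wave
elastography estimates tissue shear modulus G from the propagation speed c
of induced shear waves (G = ρc²), but a small, mildly stiff lesion can
produce too little contrast against the background to be conspicuous.
Because tumor tissue strain-hardens far more strongly than benign tissue,
*pre-compressing* the breast amplifies the modulus contrast
C = (G_tumor − G_surr)/G_surr.  This package reproduces that experiment
end-to-end, in silico:

1. **Phantom** — a semi-elliptical cross-section (100 × 40 mm) with a
   10 mm circular tumor; both tissues follow a second-order polynomial
   (generalized Mooney–Rivlin) strain-energy function
   `U = Σ C_ij (Ī₁−3)^i (Ī₂−3)^j + Σ (1/D_i)(J−1)^{2i}` with published
   ex vivo breast coefficients (initial shear moduli μ0 = 2(C10+C01):
   5.64 kPa tumor, 1.50 kPa benign; ν = 0.495, ρ = 1000 kg/m³).
2. **Compression** — quasi-static plane-strain finite elements: a rigid
   45 mm frictionless platen descends 0–30% of the model height onto the
   fixed-base phantom (penalty contact, selective reduced integration for
   near-incompressibility, adaptive Newton with line search).
3. **Waves** — a 3 mm wide, 180 µs downward body-force push at the
   midline launches planar shear waves through the pre-strained medium;
   linear propagation on the deformed configuration with the local
   *tangent* shear modulus, recorded at 125 µs / 0.2 mm.
4. **Reconstruction** — frequency–wavenumber directional filtering
   removes reflections; time-of-flight (arrival-time vs position slope,
   3 mm kernels, 2 × 2 mm median filter) gives the speed map; G = ρc²;
   ROI averages over the tumor disc and a same-size background disc give
   the per-level contrast.

The library is used from Python; see `examples/` for one short script per
capability.  A thin CLI (`nlswei run --config paper --out results`) wraps
the full experiment driver.

## Worked example

```python
from nlswei import fast_config, run_experiment, speed_increase_ratio

report = run_experiment(fast_config(levels=[0.0, 0.15]))
print(report.table[["level", "g_tumor", "g_surr", "contrast"]])
print(speed_increase_ratio(report, 0.0, 0.15))
```

prints (coarse two-level run; exact digits depend on the config):

```
 level   g_tumor   g_surr  contrast
  0.00  4.952702 1.600233  2.094989
  0.15 18.100491 3.352626  4.398899
1.33
```

Read: at 0% compression the reconstructed tumor modulus (≈5.0 kPa) is close
to its analytic μ0 = 5.64 kPa and the background to its 1.5 kPa; by 15%
compression the tumor has strain-hardened nearly four-fold while the
background barely doubled, so the contrast rises sharply — the effect that
makes the lesion conspicuous.  The last number is the ratio of the tumor's
wave-speed increase factor to the background's over the same interval.

The homogeneous control is in `examples/04_shear_wave_tof.py`: a uniform
4 kPa phantom reconstructs to within a few percent of the analytic
2.000 m/s shear speed, validating the wave + TOF chain against the closed
form c = √(μ/ρ).

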