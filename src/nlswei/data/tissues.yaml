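# Second-order polynomial hyperelastic coefficients for breast tissue,
# from published ex vivo breast-tissue measurements.  Values are stored on
# the MPa scale (unit_scale_kpa converts to kPa internally); the initial
# shear modulus of each tissue is mu0 = 2*(c10 + c01).
unit_scale_kpa: 1000.0
poisson_ratio: 0.495
tissues:
  tumor:        # malignant tumor (hard, strongly strain-hardening)
    c10: 1.41e-3
    c01: 1.41e-3
    c11: 17.1e-2
    c20: 1.66e-2
    c02: 1.66e-2
  benign:       # benign breast tissue (soft background)
    c10: 0.375e-3
    c01: 0.375e-3
    c11: 0.256e-2
    c20: 0.0283e-2
    c02: 0.0283e-2
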