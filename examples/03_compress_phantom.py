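"""Quasi-static platen compression of a small phantom.

Compresses a reduced-size heterogeneous phantom to 10% and 20% with the
frictionless rigid platen and prints the per-tissue averages of strain,
vertical stress and tangent shear modulus.  The stiff inclusion deforms
less than the background but carries more stress, and both tissues
stiffen with compression (the tumor much faster).
"""

from nlswei import build_phantom, roi_statistics, staged_compression

phantom = build_phantom(tumor_center=(6.0, 10.0), tumor_diameter=5.0,
                        platen_width=22.0)
states = staged_compression(phantom, [0.0, 0.10, 0.20], spacing=2.0,
                            substep=0.02)

print("level  tissue        strain[%]  stress[kPa]  mu_t[kPa]")
for st in states:
    r = roi_statistics(st, phantom, surr_offset=(5.0, 0.0))
    for name in ("tumor", "surrounding"):
        row = r[name]
        print(f"{st.compression_level:5.2f}  {name:12s}  "
              f"{row['strain_mean']:7.1f}    {row['stress_mean']:8.2f}   "
              f"{row['modulus_mean']:8.2f}")
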