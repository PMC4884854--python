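"""Build the breast phantom and inspect its label map.

The phantom is a semi-elliptical cross-section, 100 mm wide and 40 mm
high, with a 10 mm stiff circular tumor centered 20 mm above the base and
38 mm from the right edge.  The label map can be rasterized at any grid
spacing; the numbers below check the discretized tumor area against the
analytic disc area.
"""

import numpy as np

from nlswei import build_phantom
from nlswei.phantom import BACKGROUND, TUMOR, VOID

phantom = build_phantom()
labels, xs, ys = phantom.rasterize(0.2)

area_tumor = (labels == TUMOR).sum() * 0.2 ** 2
area_total = (labels != VOID).sum() * 0.2 ** 2
print(f"grid: {labels.shape[0]} x {labels.shape[1]} cells at 0.2 mm")
print(f"tumor area      {area_tumor:8.1f} mm^2 (analytic {np.pi * 25:.1f})")
print(f"phantom area    {area_total:8.1f} mm^2 (analytic {np.pi * 50 * 40 / 2:.1f})")
print(f"tumor center    {phantom.tumor_center} mm "
      f"(20 mm above base, 38 mm from right edge)")
print(f"materials       background mu0 = {phantom.materials[BACKGROUND].mu0:.2f} kPa, "
      f"tumor mu0 = {phantom.materials[TUMOR].mu0:.2f} kPa")
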