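"""Grow a CTV/PTV margin ladder around a tumor mask.

A clinical target volume (CTV) adds an isotropic microscopic-spread margin
to the imaged tumor; the planning target volume (PTV) adds a further 5 mm
setup margin.  For a spherical tumor the expanded volumes can be checked
against the closed form (4/3)*pi*r^3.
"""

import numpy as np

from fetrelapse import BinaryMask, GridSpec, build_ctv, build_ptv
from fetrelapse.phantom import sphere_volume_ml

grid = GridSpec(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0))
xx, yy, zz = np.meshgrid(*(np.arange(n) for n in grid.shape), indexing="ij")
tumor = BinaryMask(grid, (xx - 32) ** 2 + (yy - 32) ** 2 + (zz - 32) ** 2 <= 10**2)

print(f"tumor: {tumor.volume_ml:.2f} ml (analytic {sphere_volume_ml(10):.2f} ml)")
print("margin   CTV [ml]   PTV [ml]   analytic CTV [ml]")
for margin in (0.0, 5.0, 7.0, 10.0):
    ctv = build_ctv(tumor, margin)
    ptv = build_ptv(ctv, setup_margin_mm=5.0)
    print(
        f"{margin:4.0f} mm  {ctv.volume_ml:8.2f}  {ptv.volume_ml:9.2f}"
        f"  {sphere_volume_ml(10 + margin):8.2f}"
    )

# Each CTV volume tracks the analytic sphere of radius (10 + margin) mm to
# within one voxel-shell; the PTV column is the same ladder shifted by the
# additional 5 mm setup margin.
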