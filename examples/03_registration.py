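"""Recover a known rigid pose of the reference screw.

Volume loss and the peri-implant shells need the non-degraded reference
screw on the degraded scan's grid.  Here a known pose plus 2-voxel
surface erosion (mimicking corrosion) is applied, then recovered by
Dice-maximizing registration.
"""

import numpy as np
from scipy import ndimage

from osseoquant import (
    ReferenceScrew,
    RigidTransform,
    ScrewSpec,
    generate_screw,
    register_reference,
    resample_labels,
)

spec = ScrewSpec()
spacing = 0.1
reference = generate_screw(spec, spacing)

applied = RigidTransform(rotation_deg=(0.0, 5.0, 0.0), translation_mm=(1.0, -0.6, 0.3),
                         center_mm=(spec.length / 2, 0.0, 0.0))
grid = generate_screw(spec, spacing, margin_mm=2.2)
target = resample_labels(reference, applied, grid)
target = target.like(ndimage.binary_erosion(target.labels != 0, iterations=2).astype(np.uint8))

result = register_reference(ReferenceScrew(reference), target)

rel = result.transform.matrix @ applied.matrix.T
angle_err = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
center = np.array([[spec.length / 2, 0.0, 0.0]])
translation_err = np.abs(result.transform.apply(center) - applied.apply(center)).max()

print(f"applied pose : rot {applied.rotation_deg} deg, t {applied.translation_mm} mm")
print(f"overlap Dice : {result.dice:.4f} (init {result.dice_init:.4f})")
print(f"rotation err : {angle_err:.2f} deg")
print(f"translation err at screw center: {translation_err:.3f} mm (voxel = {spacing} mm)")
# Translation is recovered to a small fraction of a voxel.  The eroded
# 0.2 mm of surface leaves the rotation determined only up to the erosion
# slack (a couple of degrees at this voxel size); finer grids pin it tighter.
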