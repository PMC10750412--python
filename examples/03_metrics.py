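"""Score a reconstruction: overlap, distance and asymmetry metrics.

SDI (Sørensen–Dice, %) measures voxel overlap between a predicted
model P and ground truth G; the directed Hausdorff distance is the
worst-case gap from G's bone voxels to P's. With anisotropic voxels
one lattice HD unit spans a physical range — for 0.45 x 0.45 x 0.8 mm
voxels, 0.45 to 1.0223 mm. The cranial-vault asymmetry indices
(ACVAI/PCVAI) compare diagonal radii at +-60 degrees from the midline
on the axial plane that intersects the implant the most.
"""

import numpy as np

from craniofill.defects import make_defect_pairs
from craniofill.metrics import (
    cvai_diagonals,
    cvai_indices,
    directed_hausdorff,
    hd_unit_range,
    sdi,
    select_measurement_plane,
)
from craniofill.phantom import PhantomSpec, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=4))
pair = make_defect_pairs(phantom, n_variants=1, rng=4)[0]
truth = pair.implant_truth

# a deliberately imperfect "prediction": the truth eroded by one voxel
from scipy import ndimage

pred_values = ndimage.binary_erosion(truth.values).astype(np.uint8)
from craniofill.volume import BinaryVolume

pred = BinaryVolume(pred_values, truth.spacing)
print(f"implant truth: {truth.ones_count()} voxels, eroded prediction: "
      f"{pred.ones_count()} voxels")
print(f"SDI = {sdi(pred, truth):.2f} %  (100 % would be a perfect overlap)")
print(f"directed HD (lattice) = {directed_hausdorff(truth, pred):.3f} units")
print(f"directed HD (mm)      = {directed_hausdorff(truth, pred, in_mm=True):.3f} mm")

lo, hi = hd_unit_range((0.45, 0.45, 0.8))
print(f"for 0.45x0.45x0.8 mm voxels, 1 HD unit spans {lo:.4f}..{hi:.4f} mm")

plane = select_measurement_plane(truth)
m = cvai_diagonals(phantom, plane)
print(f"measurement plane (most implant voxels): slice {plane}")
print(f"diagonals AO={m.AO:.1f} BO={m.BO:.1f} CO={m.CO:.1f} DO={m.DO:.1f} mm")
print(f"ACVAI={m.acvai:.2f}% PCVAI={m.pcvai:.2f}%  (0% = perfectly symmetric vault)")

# the published clinical worked example: lengths in, indices out
acvai, pcvai = cvai_indices(71.05, 72.63, 83.70, 85.53)
print(f"reference lengths (71.05, 72.63, 83.70, 85.53) mm -> "
      f"ACVAI {acvai:.2f} %, PCVAI {pcvai:.2f} %")
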