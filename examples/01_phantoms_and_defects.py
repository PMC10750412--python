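"""Generate a synthetic cranial-vault phantom and carve defects from it.

The phantom is an asymmetric ellipsoidal bone shell cropped below a
horizontal base plane; defects are Boolean subtractions of parametric
masks (60-120 mm diameter) whose removed bone doubles as the
ground-truth implant.
"""

import numpy as np

from craniofill.defects import make_defect_pairs, rotate_augment
from craniofill.phantom import PhantomSpec, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=1))
print(f"phantom grid {phantom.shape}, spacing {phantom.spacing} mm")
print(f"bone voxels: {phantom.ones_count()} "
      f"({100 * phantom.ones_count() / phantom.values.size:.1f}% occupancy)")

pairs = make_defect_pairs(phantom, n_variants=25, rng=1)
sizes = [p.implant_truth.ones_count() for p in pairs]
print(f"{len(pairs)} defect variants; implant sizes "
      f"{min(sizes)}..{max(sizes)} voxels (median {int(np.median(sizes))})")
# conservation: defective + implant = intact, voxel for voxel
p0 = pairs[0]
assert p0.defective.ones_count() + p0.implant_truth.ones_count() == phantom.ones_count()

variants = rotate_augment(phantom)  # 2-degree steps, 3 per side
print(f"rotation augmentation: {len(variants)} variants "
      f"(voxel counts {[v.ones_count() for v in variants]})")
print("each variant is the same skull yawed by k*2 degrees; counts stay close")
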