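"""Voxelwise T1/amplitude mapping of a synthetic brain volume stack.

Generates a three-compartment brain phantom (WM/GM/CSF T1 of
0.85/1.29/4.58 s) imaged at 16 flip angles (TR = 11 ms) with realistic
image noise, fits all voxels in one vectorized pass restricted to the
bias-free angle range (<= 18 degrees), and reports compartment medians.
"""

import numpy as np

from vfalin import (NoiseModel, brain3c_phantom, fit_volume,
                    generate_phantom_volumes, protocol_preset)

phantom = brain3c_phantom((24, 24, 24))
tr, angles = protocol_preset("exp4")
stack = generate_phantom_volumes(
    phantom, angles, tr, noise=NoiseModel(0.001), seed=1
)
maps = fit_volume(stack, alpha_max=18.0)

print(f"fitted {int(maps.mask.sum())} of {maps.mask.size} voxels "
      f"(background auto-masked), {len(angles)} -> "
      f"{int(np.max(maps.nfit))} volumes after angle selection")
names = {1: "WM ", 2: "GM ", 3: "CSF"}
for lab, (t1_true, _) in phantom.compartments.items():
    sel = (phantom.labels == lab) & maps.mask
    med = np.nanmedian(maps.t1[sel])
    print(f"  {names[lab]}: median T1 = {med:.3f} s (truth {t1_true:.2f} s, "
          f"{sel.sum()} voxels)")
print("medians recover the ground truth; per-voxel spread grows with T1 "
      "because TR/T1 (hence the signal) shrinks.")
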