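"""Recover a known rigid misalignment by normalized mutual information.

A phantom T1w volume is misaligned from the FLAIR reference by a known
rigid transform; multi-resolution NMI registration should recover it to
a fraction of a voxel and a fraction of a degree.
"""

import numpy as np

from wmhseg import PhantomSpec, generate_phantom, rigid_register

spec = PhantomSpec(misalign={"T1w": (3.0, 3.0, -2.0, 6.0)}, seed=4)
phantom = generate_phantom(spec)

fitted, info = rigid_register(phantom.t1w, phantom.flair, return_info=True)
injected = phantom.transforms["T1w"]

print("injected translation (mm):", injected.translation)
print("fitted   translation (mm):", fitted.translation.round(3))
print("injected rotation (deg):", np.rad2deg(injected.rotation).round(3))
print("fitted   rotation (deg):", np.rad2deg(fitted.rotation).round(3))
print(f"final NMI {info.nmi:.4f} after {info.n_evaluations} metric evaluations")

err_vox = np.abs(fitted.translation - injected.translation) / phantom.flair.spacing
err_deg = np.abs(np.rad2deg(fitted.rotation - injected.rotation))
print(f"max error: {err_vox.max():.3f} voxels, {err_deg.max():.3f} degrees")
# Errors well below 0.5 voxel / 0.5 degree mean the T1w and DWI volumes
# can be mapped onto the FLAIR grid accurately enough for voxelwise fusion.
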