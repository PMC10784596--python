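"""Register the model onto a ground-truth phantom and inspect the fit.

A phantom poses the model landmarks with a known random affine transform
and quantizes the target coordinates to a 0.3 mm CT voxel grid.  The
quasi-Newton registration should recover the pose up to the quantization
noise: the reported MAE (mean 3D distance per landmark pair, mm) stays
below the scanner resolution.
"""

import numpy as np

from cochreg import PhantomSpec, make_phantom, register

phantom = make_phantom(PhantomSpec(seed=42, noise="quantize"))
result = register(phantom.model_landmarks, phantom.target_landmarks)

print(f"landmark pairs : {len(phantom.model_landmarks)}")
print(f"iterations     : {result.iterations}")
print(f"final SSD      : {result.final_ssd:.6f} mm^2")
print(f"MAE            : {result.mae:.4f} mm  (CT voxel edge: 0.3 mm)")
print(f"matrix error   : {np.abs(result.matrix - phantom.true_matrix).max():.2e} "
      "(max abs entry difference vs the true pose)")
for label, err in sorted(result.per_landmark_error.items()):
    print(f"  landmark {label:2d}: {err:.4f} mm")
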