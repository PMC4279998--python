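"""Inspect the Hessian shape features on analytic structures.

lambda_ratio is high on tube axes and ~0 on blobs and background, and the
corrected eigenvector e3' points along a tube's axis — together they let an
edit distinguish fibres by orientation and reject somata.
"""

import numpy as np

import localtf as lt

direction = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
tube, mask = lt.make_tube((32, 32, 32), (16, 16, 16), direction, radius=2.0, peak=0.9)
fv = lt.build_feature_volume(tube)

axis = tube.data >= 0.9 * tube.data.max()
print(f"tube along (1,1,0)/sqrt(2): lambda_ratio on axis = "
      f"{fv.lambda_ratio[axis].mean():.3f} (background {fv.lambda_ratio[~mask].mean():.3f})")
print(f"mean |e3' . axis| on the axis = {np.abs(fv.e3[axis] @ direction).mean():.4f} "
      f"(1.0 would be perfect alignment)")

sphere, _ = lt.make_sphere((25, 25, 25), (12, 12, 12), radius=4.0, peak=0.9)
sfv = lt.build_feature_volume(sphere)
print(f"sphere center: lambda_ratio = {sfv.lambda_ratio[12, 12, 12]:.3f} "
      f"(isotropic curvature: lambda2/lambda1 ~ lambda3/lambda1, difference ~ 0)")
print(f"sigma(lambda_ratio) over the tube volume = {fv.sigma_lambda:.4f} "
      f"(the scale used by the lambda_ratio dissimilarity metric)")
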