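"""Reveal one fibre orientation family with a localized orientation edit.

A reference voxel x0 on a dim-family tube defines the wanted orientation;
brushing a small ROI around it with sensitivity alpha = 10 and pointer
radius beta = 6 shifts the effective intensity of similarly-oriented voxels
inside the ROI up to the reference appearance, while crossing fibres and
distant regions are untouched.
"""

import numpy as np

import localtf as lt

scene = lt.make_crossing_scene(seed=42)
features = lt.build_feature_volume(scene.volume)
tf = lt.TransferFunction1D.grayscale_ramp(threshold=0.2, full=0.9)
view = lt.RenderSettings(eye_direction=(0, 0, -1))

# exemplar: a voxel on a dim-family (family 1) tube axis with defined e3'
sid, meta = next((s, m) for s, m in scene.structures.items() if m["family"] == 1)
point, direction = np.asarray(meta["point"]), np.asarray(meta["direction"])
x0 = None
for t in sorted(np.arange(-80, 80, 0.25), key=abs):  # nearest the tube's midpoint first
    idx = tuple(int(v) for v in np.rint(point + t * direction))
    if all(0 <= idx[a] < 96 for a in range(3)) and np.any(features.e3[idx]):
        x0 = idx
        break

edit = lt.EditOperation(x0, (x0,), alpha=10.0, beta=6.0, metric="orientation")
shift = lt.compute_shift_field(scene.volume, features, edit)

base = lt.render(scene.volume, None, tf, view)
edited = lt.render(scene.volume, shift, tf, view)
lt.save_png(edited, "phantom_edited.png")

changed = np.abs(edited - base).max(axis=-1) > 1.0 / 255.0
print(f"reference x0 = {x0} on a dim tube along "
      f"{tuple(float(v) for v in np.round(direction, 3))}")
print(f"shift field: max delta = {shift.delta.max():.3f} "
      f"(raises ~0.2-intensity voxels to the ~{scene.volume.data[x0]:.2f} reference)")
print(f"{changed.sum()} pixels changed, all within the brushed ROI; "
      f"max in-plane distance of a changed pixel from x0 = "
      f"{max(np.hypot(x - x0[0], y - x0[1]) for y, x in np.argwhere(changed)):.1f} voxels "
      f"(beta = 6 sigmoid tail)")
print("wrote phantom_edited.png")
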