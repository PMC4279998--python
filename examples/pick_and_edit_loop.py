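"""Close the interactive loop: pick a 3-D point on the render, edit there.

Picking marches the clicked pixel's ray and accumulates shifted-TF opacity
until a threshold: the returned voxel sits on the visible surface.  Because
opacities include the current shift, structures revealed by an edit are
themselves pickable — the picked voxel can seed the next edit.
"""

import numpy as np

import localtf as lt
from localtf.shift import ShiftField

tf = lt.TransferFunction1D.grayscale_ramp(threshold=0.2, full=0.9)
view = lt.RenderSettings(eye_direction=(0, 0, -1), background=(0, 0, 0, 0))

# a dim slab (intensity 0.1) the preset cannot show
data = np.zeros((16, 16, 16))
data[:, :, 6:9] = 0.1
vol = lt.ScalarVolume(data)

before = lt.pick(vol, None, tf, view, (8, 8), alpha_th=0.3)
print(f"pick at pixel (8, 8) without any edit: hit = {before.hit} "
      f"(accumulated opacity {before.accumulated_opacity:.3f} < 0.3)")

# an edit-style shift that raises the slab to visible intensity
shift = ShiftField(np.where(vol.data > 0, 0.8, 0.0))
after = lt.pick(vol, shift, tf, view, (8, 8), alpha_th=0.3)
print(f"same pick with the shift applied: hit = {after.hit}, "
      f"voxel = {after.position} (top face of the slab at z = 8)")
print("-> the picked voxel can be passed back as x0 or a stroke center "
      "for the next edit")
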