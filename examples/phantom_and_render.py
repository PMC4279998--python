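"""Generate a crossing-tube phantom and render it with a 1-D preset.

The scene emulates a two-photon stack: a bright fibre family along (1,1,0),
a low-contrast family along (1,-1,0), a vessel-shadowed central region and
additive noise.  With only an intensity ramp preset, the dim family is
nearly invisible — the problem the localized TF shift solves.
"""

import numpy as np

import localtf as lt

scene = lt.make_crossing_scene(seed=42)
tf = lt.TransferFunction1D.grayscale_ramp(threshold=0.2, full=0.9)
image = lt.render(scene.volume, None, tf, lt.RenderSettings(eye_direction=(0, 0, -1)))
lt.save_png(image, "phantom_preset.png")

bright = sum(m["family"] == 0 for m in scene.structures.values())
dim = sum(m["family"] == 1 for m in scene.structures.values())
visible = (image[..., :3].max(axis=-1) > 0.1).sum()
print(f"scene: {bright} bright tubes (peak 0.9), {dim} dim tubes (peak 0.45), "
      f"shadow factor 0.4, noise sd 0.02")
print(f"preset-only render: {visible} of {image.shape[0] * image.shape[1]} pixels lit")
print("-> the dim (1,-1,0) family contributes almost nothing: its intensities "
      "sit below the preset's 0.2 visibility threshold, especially in the shadow")
print("wrote phantom_preset.png")
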