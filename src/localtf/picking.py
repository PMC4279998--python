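"""3-D picking on the rendered image by opacity accumulation.

A 2-D click is mapped back to the voxel the user meant by marching from the
click pixel along the viewing direction, summing the per-sample opacities
alpha_i obtained through the *shifted* transfer function, and acquiring the
first sample at which the running sum reaches a threshold alpha_th.  Because
the opacities include the local edit Delta, structures that are visible only
through an edit are pickable, which is what closes the point-and-edit loop:
the picked voxel can serve as the next x0 or stroke center.

The accumulation is the plain sum of sample opacities, not the composited
transmittance; the threshold marks "enough opaque material seen", i.e. the
surface of the visualised structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .render import RenderSettings, _ray_layout, _sampled_rgba
from .shift import ShiftField
from .volume_io import ScalarVolume, TransferFunction1D

__all__ = ["PickResult", "pick"]


@dataclass(frozen=True)
class PickResult:
    """Outcome of a pick: acquired voxel, accumulated opacity and threshold."""

    position: tuple[int, int, int] | None
    accumulated_opacity: float
    threshold: float
    hit: bool


def pick(
    vol: ScalarVolume,
    shift: ShiftField | None,
    tf: TransferFunction1D,
    settings: RenderSettings,
    x_click: tuple[int, int],
    alpha_th: float = 0.3,
) -> PickResult:
    """Map a click pixel to the 3-D surface voxel of the visible structure.

    Marches the click pixel's ray at the renderer's sampling interval,
    accumulating the shifted-TF opacity of each sample; returns the first
    sample where the sum reaches ``alpha_th`` (rounded to the nearest voxel
    index), or a miss when the ray never accumulates that much.
    """
    if not (0 < alpha_th <= 1):
        raise ValueError("alpha_th must be in (0, 1]")
    origins, d, t_values, (W, H) = _ray_layout(vol.shape, settings)
    px, py = int(x_click[0]), int(x_click[1])
    if not (0 <= px < W and 0 <= py < H):
        raise ValueError(f"click {x_click} outside the {W}x{H} image")
    ray_index = py * W + px
    origin = origins[ray_index : ray_index + 1]
    rgba = _sampled_rgba(vol, shift, tf, settings, origin, d, t_values)
    alphas = rgba[:, 0, 3]
    acc = np.cumsum(alphas)
    crossed = np.nonzero(acc >= alpha_th)[0]
    if crossed.size == 0:
        total = float(acc[-1]) if acc.size else 0.0
        return PickResult(None, total, alpha_th, False)
    k = int(crossed[0])
    point = origin[0] + t_values[k] * d
    idx = np.rint(point).astype(int)
    idx = np.clip(idx, 0, np.asarray(vol.shape) - 1)
    return PickResult(tuple(int(v) for v in idx), float(acc[k]), alpha_th, True)
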