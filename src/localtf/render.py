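"""CPU orthographic ray-casting volume renderer.

One parallel ray per pixel travels along the viewing direction ``nu_eye``;
intensity and shift are sampled by trilinear interpolation at a fixed step,
mapped through the shifted transfer function, and composited front to back
under the emission-absorption model with opacity correction

    a' = 1 - (1 - a) ** (step / reference_step)

so halving the step does not brighten the image.  Rays march in voxel index
space; for the axis-aligned view presets the pixel grid coincides with the
in-plane voxel grid (pixel (px, py) of a -z view looks down the voxel
column x = px, y = py).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .shift import ShiftField, evaluate_shifted_tf
from .volume_io import ScalarVolume, TransferFunction1D

__all__ = ["RenderSettings", "composite_ray", "render", "sample_opacities", "save_png"]


@dataclass(frozen=True)
class RenderSettings:
    """Camera and sampling parameters for the orthographic ray caster."""

    eye_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    image_size: tuple[int, int] | None = None  # None: in-plane volume dims
    step: float = 0.5
    reference_step: float = 1.0
    background: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)
    early_termination_alpha: float = 0.99

    def __post_init__(self) -> None:
        d = np.asarray(self.eye_direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0 or not np.all(np.isfinite(d)):
            raise ValueError("eye_direction must be a non-zero finite vector")
        object.__setattr__(self, "eye_direction", tuple(d / n))
        if self.step <= 0 or self.reference_step <= 0:
            raise ValueError("step and reference_step must be > 0")
        if not (0 < self.early_termination_alpha <= 1):
            raise ValueError("early_termination_alpha must be in (0, 1]")


def view_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right/up image-plane basis (u, v) for a view direction.

    Axis-aligned directions use the cyclic convention x->(y, z), y->(z, x),
    z->(x, y) regardless of sign, so the pixel grid maps directly onto the
    two in-plane voxel axes; oblique directions fall back to Gram-Schmidt.
    """
    d = np.asarray(direction, dtype=np.float64)
    axis = int(np.argmax(np.abs(d)))
    if abs(abs(d[axis]) - 1.0) < 1e-9:
        u = np.zeros(3)
        v = np.zeros(3)
        u[(axis + 1) % 3] = 1.0
        v[(axis + 2) % 3] = 1.0
        return u, v
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _default_image_size(shape: tuple[int, int, int], u: np.ndarray, v: np.ndarray) -> tuple[int, int]:
    extent = np.asarray(shape, dtype=np.float64)
    w = int(np.ceil(np.abs(u) @ extent))
    h = int(np.ceil(np.abs(v) @ extent))
    return max(w, 1), max(h, 1)


def _ray_layout(shape: tuple[int, int, int], settings: RenderSettings):
    """Per-pixel ray origins plus the common sample parameterisation.

    Returns ``(origins, direction, t_values, (W, H))`` with ``origins`` of
    shape (H*W, 3) lying on the image plane through the volume center and
    ``t_values`` a shared 1-D grid covering every ray's box intersection.
    """
    d = np.asarray(settings.eye_direction, dtype=np.float64)
    u, v = view_basis(d)
    W, H = settings.image_size or _default_image_size(shape, u, v)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    px = np.arange(W) - (W - 1) / 2.0
    py = np.arange(H) - (H - 1) / 2.0
    PX, PY = np.meshgrid(px, py, indexing="xy")
    origins = center + PX[..., None] * u + PY[..., None] * v  # (H, W, 3)
    origins = origins.reshape(-1, 3)
    # slab intersection with the sampling box [0, n-1] per axis
    lo = np.zeros(3)
    hi = np.asarray(shape, dtype=np.float64) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - origins) / d
        t2 = (hi - origins) / d
    tlo = np.minimum(t1, t2)
    thi = np.maximum(t1, t2)
    parallel = np.abs(d) < 1e-15
    inside = (origins >= lo) & (origins <= hi)
    tlo = np.where(parallel, np.where(inside, -np.inf, np.inf), tlo)
    thi = np.where(parallel, np.where(inside, np.inf, -np.inf), thi)
    tmin = np.max(tlo, axis=1)
    tmax = np.min(thi, axis=1)
    hit = tmax >= tmin
    if not np.any(hit):
        t_values = np.zeros(0)
    else:
        t0 = float(np.min(tmin[hit]))
        t_end = float(np.max(tmax[hit]))
        n_steps = max(int(np.ceil((t_end - t0) / settings.step)) + 1, 1)
        t_values = t0 + settings.step * np.arange(n_steps)
    return origins, d, t_values, (W, H)


def _sample(data: np.ndarray, pts: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at (N, 3) points; invalid points -> 0."""
    out = ndimage.map_coordinates(data, pts.T, order=1, mode="nearest")
    out[~valid] = 0.0
    return out


def _sampled_rgba(vol, shift, tf, settings, origins, d, t_values):
    """Shifted-TF RGBA at every (sample, ray); invalid samples transparent."""
    n_rays = origins.shape[0]
    n_t = t_values.size
    rgba = np.zeros((n_t, n_rays, 4))
    hi = np.asarray(vol.shape, dtype=np.float64) - 1.0
    for k in range(n_t):
        pts = origins + t_values[k] * d
        valid = np.all((pts >= 0) & (pts <= hi), axis=1)
        if not np.any(valid):
            continue
        I = _sample(vol.data, pts, valid)
        delta = _sample(shift.delta, pts, valid) if shift is not None else 0.0
        s = evaluate_shifted_tf(tf, I, delta, vol.intensity_domain)
        s[~valid] = 0.0
        rgba[k] = s
    return rgba


def composite_ray(
    samples: np.ndarray,
    step: float,
    reference_step: float = 1.0,
    background: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0),
    early_termination_alpha: float = 0.99,
) -> np.ndarray:
    """Front-to-back emission-absorption compositing of one ray.

    ``samples`` is an (N, 4) RGBA array ordered front to back.  Accumulation
    stops once the accumulated opacity reaches the early-termination cutoff;
    the remaining transmittance is filled with the background.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    C = np.zeros(3)
    A = 0.0
    exponent = step / reference_step
    for rgba in samples:
        if A >= early_termination_alpha:
            break
        a = 1.0 - (1.0 - rgba[3]) ** exponent
        C = C + (1.0 - A) * a * rgba[:3]
        A = A + (1.0 - A) * a
    bg = np.asarray(background, dtype=np.float64)
    C = C + (1.0 - A) * bg[3] * bg[:3]
    A = A + (1.0 - A) * bg[3]
    return np.concatenate([C, [A]])


def render(
    vol: ScalarVolume,
    shift: ShiftField | None,
    tf: TransferFunction1D,
    settings: RenderSettings = RenderSettings(),
) -> np.ndarray:
    """Render the volume through the (optionally shifted) preset.

    Returns an (H, W, 4) RGBA image in [0, 1]; deterministic for fixed
    inputs.
    """
    if shift is not None and shift.shape != vol.shape:
        raise ValueError("volume and shift field grids differ")
    origins, d, t_values, (W, H) = _ray_layout(vol.shape, settings)
    rgba = _sampled_rgba(vol, shift, tf, settings, origins, d, t_values)
    n_rays = origins.shape[0]
    C = np.zeros((n_rays, 3))
    A = np.zeros(n_rays)
    exponent = settings.step / settings.reference_step
    for k in range(t_values.size):
        active = A < settings.early_termination_alpha
        if not np.any(active):
            break
        a = 1.0 - (1.0 - rgba[k, :, 3]) ** exponent
        a = np.where(active, a, 0.0)
        C += ((1.0 - A) * a)[:, None] * rgba[k, :, :3]
        A += (1.0 - A) * a
    bg = np.asarray(settings.background, dtype=np.float64)
    C += ((1.0 - A) * bg[3])[:, None] * bg[:3]
    A += (1.0 - A) * bg[3]
    image = np.concatenate([C, A[:, None]], axis=1).reshape(H, W, 4)
    return np.clip(image, 0.0, 1.0)


def sample_opacities(
    vol: ScalarVolume,
    shift: ShiftField | None,
    tf: TransferFunction1D,
    settings: RenderSettings = RenderSettings(),
) -> np.ndarray:
    """Raw (uncorrected) per-sample opacities along every pixel's ray.

    Returns an (H, W, K) array: ``out[py, px, k]`` is the shifted-TF opacity
    of sample k on the ray of pixel (px, py).  This is the quantity the
    picking operator sums and a convenient basis for opacity-mass studies.
    """
    origins, d, t_values, (W, H) = _ray_layout(vol.shape, settings)
    rgba = _sampled_rgba(vol, shift, tf, settings, origins, d, t_values)
    return rgba[:, :, 3].T.reshape(H, W, t_values.size)


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write an RGBA image in [0, 1] as an 8-bit PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)
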