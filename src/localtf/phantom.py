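"""Seeded synthetic phantoms of crossing neural fibres.

The scenes emulate what a cortical two-photon stack looks like to this
pipeline: bright tubes with Gaussian cross-sections (point-spread blur)
running in the xy plane in two orientation families that criss-cross, one
family rendered at much lower contrast inside a "vessel shadow" region
(tissue under a blood vessel absorbs excitation light), spheres for somata,
and additive Gaussian noise.  Every voxel carries a ground-truth structure
label, which is what makes the selectivity of an orientation edit
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import ScalarVolume

__all__ = ["PhantomScene", "make_tube", "make_sphere", "make_crossing_scene"]


@dataclass(frozen=True)
class PhantomScene:
    """A labelled synthetic scene: volume, per-voxel structure id, metadata."""

    volume: ScalarVolume
    labels: np.ndarray  # int, 0 = background, same grid as volume
    structures: dict  # id -> {"kind", "family", "direction"/"center", "radius", "peak"}
    shadow_mask: np.ndarray  # bool, voxels inside the attenuated region
    seed: int


def _grid(shape: Sequence[int]) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _line_distance_sq(pts: np.ndarray, point: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = pts - point
    along = rel @ direction
    return np.sum(rel * rel, axis=-1) - along * along


def make_tube(
    shape: Sequence[int],
    point: Sequence[float],
    direction: Sequence[float],
    radius: float = 2.0,
    peak: float = 0.9,
) -> tuple[ScalarVolume, np.ndarray]:
    """A straight tube with Gaussian radial profile.

    Intensity is ``peak * exp(-dist^2 / (2 radius^2))`` where dist is the
    distance to the infinite line through ``point`` along ``direction``; the
    mask marks voxels within ``2 * radius`` of the axis.
    """
    direction = np.asarray(direction, dtype=np.float64)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("tube direction must be non-zero")
    if radius <= 0 or not (0 < peak <= 1):
        raise ValueError("need radius > 0 and peak in (0, 1]")
    direction = direction / n
    d2 = _line_distance_sq(_grid(shape), np.asarray(point, dtype=np.float64), direction)
    data = peak * np.exp(-d2 / (2.0 * radius**2))
    mask = d2 <= (2.0 * radius) ** 2
    return ScalarVolume(data), mask


def make_sphere(
    shape: Sequence[int],
    center: Sequence[float],
    radius: float = 4.0,
    peak: float = 0.9,
) -> tuple[ScalarVolume, np.ndarray]:
    """A soma-like blob with Gaussian radial profile (isotropic Hessian)."""
    if radius <= 0 or not (0 < peak <= 1):
        raise ValueError("need radius > 0 and peak in (0, 1]")
    rel = _grid(shape) - np.asarray(center, dtype=np.float64)
    d2 = np.sum(rel * rel, axis=-1)
    data = peak * np.exp(-d2 / (2.0 * radius**2))
    mask = d2 <= (2.0 * radius) ** 2
    return ScalarVolume(data), mask


def make_crossing_scene(
    shape: Sequence[int] = (96, 96, 96),
    n_tubes_per_family: int = 4,
    family_dirs: Sequence[Sequence[float]] = ((1.0, 1.0, 0.0), (1.0, -1.0, 0.0)),
    radius: float = 2.0,
    peaks: Sequence[float] = (0.9, 0.45),
    shadow_box: Sequence[Sequence[float]] | None = None,
    shadow_factor: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> PhantomScene:
    """Two criss-crossing families of in-plane tubes, shadow and noise.

    Tubes are combined by voxelwise maximum; each voxel's label is its
    argmax tube (ties to the lowest id) where that tube's mask covers it.
    Intensities inside ``shadow_box`` (default: the central slab spanning x)
    are multiplied by ``shadow_factor`` *before* zero-mean Gaussian noise of
    ``noise_sd`` is added and the result clipped to [0, 1].  The same seed
    reproduces the scene bit for bit.
    """
    dirs = [np.asarray(d, dtype=np.float64) for d in family_dirs]
    if len(dirs) != 2:
        raise ValueError("exactly two family directions expected")
    for d in dirs:
        if np.linalg.norm(d) == 0:
            raise ValueError("family direction must be non-zero")
    cross = np.linalg.norm(np.cross(dirs[0], dirs[1]))
    if cross < 1e-12:
        raise ValueError("family directions must not be parallel")
    if not (0 < shadow_factor < 1):
        raise ValueError("shadow_factor must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0

    intensities: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    structures: dict[int, dict] = {}
    sid = 0
    for fam, (d, peak) in enumerate(zip(dirs, peaks)):
        d = d / np.linalg.norm(d)
        # offsets sampled in the plane perpendicular to the tube axis
        perp1 = np.cross(d, (0.0, 0.0, 1.0))
        if np.linalg.norm(perp1) < 1e-9:
            perp1 = np.cross(d, (1.0, 0.0, 0.0))
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(d, perp1)
        half = min(shape) / 2.0 - 2.0 * radius
        for _ in range(n_tubes_per_family):
            o1, o2 = rng.uniform(-half, half, size=2)
            point = center + o1 * perp1 + o2 * perp2
            sid += 1
            vol, mask = make_tube(shape, point, d, radius, peak)
            intensities.append(vol.data)
            masks.append(mask)
            structures[sid] = {
                "kind": "tube",
                "family": fam,
                "direction": tuple(d),
                "point": tuple(point),
                "radius": radius,
                "peak": peak,
            }

    if intensities:
        stack = np.stack(intensities)
        data = stack.max(axis=0)
        best = np.argmax(stack, axis=0)  # ties -> lowest id
        covered = np.take_along_axis(np.stack(masks), best[None], axis=0)[0]
        labels = np.where(covered, best + 1, 0).astype(np.int32)
    else:
        data = np.zeros(shape)
        labels = np.zeros(shape, dtype=np.int32)

    if shadow_box is None:
        lo = np.array([0.0, shape[1] * 0.3, shape[2] * 0.3])
        hi = np.array([shape[0] - 1.0, shape[1] * 0.7, shape[2] * 0.7])
    else:
        lo = np.asarray(shadow_box[0], dtype=np.float64)
        hi = np.asarray(shadow_box[1], dtype=np.float64)
    g = _grid(shape)
    shadow_mask = np.all((g >= lo) & (g <= hi), axis=-1)
    data = np.where(shadow_mask, data * shadow_factor, data)

    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(data, 0.0, 1.0)
    return PhantomScene(ScalarVolume(data), labels, structures, shadow_mask, int(seed))
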