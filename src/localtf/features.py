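"""Hessian-based shape features for bright tubular structures.

For every voxel the 3x3 Hessian of the (Gaussian-regularised) intensity is
eigen-decomposed with eigenvalues sorted ascending by signed value,
``lambda1 <= lambda2 <= lambda3``.  On a bright tube the two transverse
curvatures are strongly negative and the axial one is near zero, so

* ``lambda_ratio = lambda2/lambda1 - lambda3/lambda1`` (when all three are
  non-positive) is close to 1 on tube axes and close to 0 on blobs and
  background, and
* ``e3``, the eigenvector of the largest eigenvalue, points along the tube
  axis.

``e3`` is zeroed wherever ``lambda1 <= lambda2 <= 0`` fails (the corrected
orientation ``e3'``), which suppresses voxels darker than their
surroundings so they can never be mistaken for bright structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import ScalarVolume

__all__ = [
    "FeatureVolume",
    "compute_hessian",
    "eigen_decompose",
    "lambda_ratio",
    "corrected_e3",
    "build_feature_volume",
]

DEFAULT_CHANNELS = ("lambda_ratio", "e3x", "e3y", "e3z")

_CHANNEL_ALIASES = {"e3": ("e3x", "e3y", "e3z")}


def expand_channels(spec: Sequence[str]) -> tuple[str, ...]:
    """Expand shorthand channel names ('e3' -> its three components)."""
    out: list[str] = []
    for name in spec:
        out.extend(_CHANNEL_ALIASES.get(name, (name,)))
    return tuple(out)


@dataclass(frozen=True)
class FeatureVolume:
    """Per-voxel feature vector C(x) plus the metric context it implies.

    Attributes
    ----------
    lambda_ratio
        ``(nx, ny, nz)`` tube-likeness in [0, 1].
    e3
        ``(nx, ny, nz, 3)`` corrected axis orientation e3'; unit length or
        exactly zero where suppressed.
    eigenvalues
        ``(nx, ny, nz, 3)`` Hessian eigenvalues, ascending.
    covariance
        Covariance matrix V of the selected channels over all voxels,
        diagonally regularised to be invertible (Mahalanobis metric).
    sigma_lambda
        Population standard deviation of lambda_ratio over the volume.
    scale
        Gaussian derivative scale in voxels.
    channel_names
        Names of the channels stacked by :meth:`channel_stack`.
    """

    lambda_ratio: np.ndarray
    e3: np.ndarray
    eigenvalues: np.ndarray
    covariance: np.ndarray
    sigma_lambda: float
    scale: float
    channel_names: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lambda_ratio.shape  # type: ignore[return-value]

    def _channel(self, name: str) -> np.ndarray:
        if name == "lambda_ratio":
            return self.lambda_ratio
        if name in ("e3x", "e3y", "e3z"):
            return self.e3[..., "xyz".index(name[-1])]
        raise KeyError(f"unknown feature channel {name!r}")

    def channel_stack(self) -> np.ndarray:
        """``(nx, ny, nz, k)`` array of the configured channels (C(x))."""
        return np.stack([self._channel(n) for n in self.channel_names], axis=-1)

    def feature_at(self, x: Sequence[int]) -> np.ndarray:
        """Feature vector C(x0) at a voxel index."""
        i, j, k = (int(v) for v in x)
        return np.array([self._channel(n)[i, j, k] for n in self.channel_names])


def _derivative_kernels(sigma: float, truncate: float = 4.0):
    """Sampled Gaussian kernels with exact discrete moment conditions.

    The smoothing kernel sums to 1; the first-derivative kernel satisfies
    sum(k) = 0 and sum(k*m) = 1; the second-derivative kernel satisfies
    sum(k) = 0 and sum(k*m^2)/2 = 1.  These corrections make the Hessian of
    any quadratic exact (in particular, identically zero on constants),
    which the raw sampled-Gaussian kernels only achieve approximately.
    """
    r = max(int(truncate * sigma + 0.5), 1)
    m = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(m**2) / (2.0 * sigma**2))
    g /= g.sum()
    k1 = m * g
    k1 /= np.sum(k1 * m)
    k2 = (m**2 / sigma**2 - 1.0) * g
    k2 -= k2.mean()
    k2 /= 0.5 * np.sum(k2 * m**2)
    return g, k1, k2


def compute_hessian(vol: ScalarVolume, scale: float = 1.0) -> np.ndarray:
    """Per-voxel symmetric Hessian via Gaussian-regularised differences.

    Returns a ``(nx, ny, nz, 3, 3)`` field.  ``scale`` is the Gaussian
    sigma in voxel units; derivatives are taken in index space (anisotropy
    is deliberately not resampled away).
    """
    scale = float(scale)
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if min(vol.shape) <= int(4 * scale):
        raise ValueError(
            f"volume shape {vol.shape} smaller than the effective Gaussian "
            f"kernel at scale {scale}"
        )
    g, k1, k2 = _derivative_kernels(scale)
    kernels = {0: g, 1: k1, 2: k2}
    H = np.empty(vol.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = vol.data
            for axis, o in enumerate(order):
                d = ndimage.correlate1d(d, kernels[o], axis=axis, mode="nearest")
            H[..., a, b] = d
            H[..., b, a] = d
    # float cancellation leaves ~1e-17 residue on structureless voxels;
    # snap it to exactly zero so they carry no curvature
    H[np.abs(H) < 1e-14] = 0.0
    return H


def eigen_decompose(hessian: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending by signed value) and eigenvectors per voxel.

    Returns ``(eigenvalues, eigenvectors)`` of shapes ``(..., 3)`` and
    ``(..., 3, 3)``; ``eigenvectors[..., :, i]`` is the unit eigenvector of
    ``eigenvalues[..., i]``, so index 2 is e3.
    """
    if not np.all(np.isfinite(hessian)):
        raise FloatingPointError("Hessian field contains non-finite entries")
    return np.linalg.eigh(hessian)


def lambda_ratio(l1: np.ndarray, l2: np.ndarray, l3: np.ndarray) -> np.ndarray:
    """Tube-likeness from sorted Hessian eigenvalues.

    ``l2/l1 - l3/l1`` when ``l1 <= l2 <= l3 <= 0``; ``l2/l1`` when
    ``l1 <= l2 <= 0 < l3``; 0 otherwise (including l1 == 0, where the
    quotients are undefined).  The result lies in [0, 1].
    """
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    l3 = np.asarray(l3, dtype=np.float64)
    if np.any(l1 > l2) or np.any(l2 > l3):
        raise ValueError("eigenvalues must be sorted ascending (l1 <= l2 <= l3)")
    safe_l1 = np.where(l1 == 0, 1.0, l1)
    tube = np.where(l1 < 0, l2 / safe_l1 - l3 / safe_l1, 0.0)
    plate = np.where(l1 < 0, l2 / safe_l1, 0.0)
    out = np.where(
        (l2 <= 0) & (l3 <= 0),
        tube,
        np.where(l2 <= 0, plate, 0.0),
    )
    return out if out.shape else out[()]


def corrected_e3(l1: np.ndarray, l2: np.ndarray, e3: np.ndarray) -> np.ndarray:
    """Zero the axis eigenvector outside bright structure.

    The orientation is kept only where ``l1 < 0`` and ``l2 <= 0`` (bright
    local structure); the degenerate flat case ``l1 == 0`` carries no
    structure and maps to the zero vector, like voxels darker than their
    surroundings.
    """
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    e3 = np.asarray(e3, dtype=np.float64)
    keep = (l1 < 0) & (l2 <= 0)
    return np.where(keep[..., None], e3, 0.0)


def build_feature_volume(
    vol: ScalarVolume,
    scale: float = 1.0,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> FeatureVolume:
    """Compute the full feature volume and its metric context.

    ``sigma_lambda`` is the population standard deviation of lambda_ratio
    over all voxels; the channel covariance V is estimated over all voxels
    and regularised by adding ``eps = 1e-6 * trace(V)/k`` (growing tenfold
    as needed) to the diagonal until it is invertible.
    """
    channel_names = expand_channels(channels)
    if not channel_names:
        raise ValueError("channel spec must name at least one feature channel")
    H = compute_hessian(vol, scale)
    eigvals, eigvecs = eigen_decompose(H)
    l1, l2, l3 = eigvals[..., 0], eigvals[..., 1], eigvals[..., 2]
    lr = lambda_ratio(l1, l2, l3)
    e3c = corrected_e3(l1, l2, eigvecs[..., :, 2])
    sigma = float(np.std(lr))
    fv = FeatureVolume(
        lambda_ratio=lr,
        e3=e3c,
        eigenvalues=eigvals,
        covariance=np.eye(len(channel_names)),
        sigma_lambda=sigma,
        scale=scale,
        channel_names=channel_names,
    )
    mat = fv.channel_stack().reshape(-1, len(channel_names))
    V = np.cov(mat.T, bias=True)
    V = np.atleast_2d(V)
    V = _regularize_covariance(V)
    object.__setattr__(fv, "covariance", V)
    return fv


def _regularize_covariance(V: np.ndarray) -> np.ndarray:
    k = V.shape[0]
    eps = 1e-6 * max(np.trace(V) / k, 1e-12)
    for _ in range(40):
        try:
            np.linalg.cholesky(V)
            if np.linalg.cond(V) < 1e12:
                return V
        except np.linalg.LinAlgError:
            pass
        V = V + eps * np.eye(k)
        eps *= 10
    raise np.linalg.LinAlgError("could not regularise feature covariance")
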