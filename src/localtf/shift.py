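"""The localized transfer-function shift.

An edit names a reference voxel ``x0`` on a structure whose appearance is
wanted, a brushed region-of-interest Omega (a union of pointer spheres
around the stroke centers), a feature metric, and two parameters:

* ``alpha`` — feature sensitivity.  ``f_F(d_F) = exp(-alpha * d_F)`` decides
  how strictly a voxel's feature vector must match the reference before its
  appearance is pulled toward the reference.
* ``beta`` — pointer radius.  ``f_E(d_E) = 1 / (1 + exp(d_E - beta))`` is a
  sigmoid gate on the distance to the nearest stroke center, 0.5 exactly at
  ``d_E = beta``.

The per-voxel shift is ``Delta(x) = (I(x0) - I(x)) * f_F * f_E``; looking the
preset up at ``I(x) + Delta(x)`` gives matching voxels inside Omega the
reference's color and opacity while leaving equal-intensity voxels (Delta
identically 0) and distant voxels (sigmoid tail) untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .features import FeatureVolume, expand_channels
from .volume_io import ScalarVolume, TransferFunction1D

log = logging.getLogger(__name__)

__all__ = [
    "EditOperation",
    "ShiftField",
    "METRICS",
    "dissim_mahalanobis",
    "dissim_dot",
    "dissim_orientation",
    "dissim_lambda_ratio",
    "f_F",
    "f_E",
    "roi_distance",
    "compute_shift_field",
    "combine_shift_fields",
    "evaluate_shifted_tf",
]

METRICS = ("orientation", "lambda_ratio", "mahalanobis", "dot")


@dataclass(frozen=True)
class EditOperation:
    """One user edit: exemplar point, brushed ROI and shift parameters."""

    x0: tuple[int, int, int]
    stroke_centers: tuple[tuple[float, float, float], ...]
    alpha: float = 10.0
    beta: float = 6.0
    metric: str = "orientation"
    channels: tuple[str, ...] | None = None  # mahalanobis / dot channel spec

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", tuple(int(v) for v in self.x0))
        centers = tuple(tuple(float(c) for c in p) for p in self.stroke_centers)
        if not centers:
            raise ValueError("an edit needs at least one stroke center")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.channels is not None:
            object.__setattr__(self, "channels", expand_channels(self.channels))
        object.__setattr__(self, "stroke_centers", centers)

    def validate_bounds(self, shape: Sequence[int]) -> None:
        pts = [self.x0, *self.stroke_centers]
        for p in pts:
            if any(not (0 <= p[a] <= shape[a] - 1) for a in range(3)):
                raise ValueError(f"edit point {p} outside volume bounds {tuple(shape)}")


@dataclass(frozen=True)
class ShiftField:
    """Per-voxel TF shift Delta(x) on the source grid."""

    delta: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: tuple[EditOperation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=np.float64)
        if delta.ndim != 3:
            raise ValueError("shift field must be 3-D")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.delta.shape  # type: ignore[return-value]

    def as_volume(self) -> ScalarVolume:
        """Wrap Delta for persistence through the volume writers."""
        lo = float(min(self.delta.min(), -1.0))
        hi = float(max(self.delta.max(), 1.0))
        return ScalarVolume(self.delta, self.spacing, (lo, hi))


# ---------------------------------------------------------------------------
# Dissimilarity metrics d_F
# ---------------------------------------------------------------------------


def dissim_mahalanobis(c_x: np.ndarray, c_x0: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Mahalanobis distance sqrt((C - C0)^T V^-1 (C - C0)).

    ``c_x`` may be a single vector or a ``(..., k)`` stack.
    """
    c_x = np.asarray(c_x, dtype=np.float64)
    c_x0 = np.asarray(c_x0, dtype=np.float64)
    Vinv = np.linalg.inv(V)
    diff = c_x - c_x0
    q = np.einsum("...i,ij,...j->...", diff, Vinv, diff)
    return np.sqrt(np.maximum(q, 0.0))


def dissim_dot(c_x: np.ndarray, c_x0: np.ndarray) -> np.ndarray:
    """Inner-product dissimilarity 1 - C(x) . C(x0) for unit feature vectors."""
    c_x = np.asarray(c_x, dtype=np.float64)
    c_x0 = np.asarray(c_x0, dtype=np.float64)
    return 1.0 - np.sum(c_x * c_x0, axis=-1)


def dissim_orientation(e3_x: np.ndarray, e3_x0: np.ndarray) -> np.ndarray:
    """Orientation dissimilarity 1 - |e3'(x) . e3'(x0)|, in [0, 1].

    Sign-invariant in both arguments.  A zero vector (an orientation
    suppressed by the brightness conditions) yields the maximal value 1, so
    suppressed voxels are never pulled toward the reference.
    """
    e3_x = np.asarray(e3_x, dtype=np.float64)
    e3_x0 = np.asarray(e3_x0, dtype=np.float64)
    return 1.0 - np.abs(np.sum(e3_x * e3_x0, axis=-1))


def dissim_lambda_ratio(lr_x: np.ndarray, lr_x0: float, sigma: float) -> np.ndarray:
    """|lambda_ratio(x) - lambda_ratio(x0)| / sigma (1-D Mahalanobis)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0 for the lambda_ratio metric")
    return np.abs(np.asarray(lr_x, dtype=np.float64) - lr_x0) / sigma


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def f_F(d_F: np.ndarray, alpha: float) -> np.ndarray:
    """Feature-sensitivity weight exp(-alpha * d_F), in (0, 1]."""
    return np.exp(-alpha * np.asarray(d_F, dtype=np.float64))


def f_E(d_E: np.ndarray, beta: float) -> np.ndarray:
    """Locality sigmoid 1 / (1 + exp(d_E - beta)); 0.5 exactly at d_E = beta."""
    return expit(beta - np.asarray(d_E, dtype=np.float64))


def roi_distance(
    x: np.ndarray,
    stroke_centers: Sequence[Sequence[float]],
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """d_E: distance from x to the nearest stroke center.

    Distances are measured in x-voxel units: each axis is weighted by
    ``spacing[a] / spacing[0]`` so that beta keeps its voxel-scale meaning
    on anisotropic grids.  ``x`` may be a point or a ``(..., 3)`` stack; a
    single center reduces to the plain Euclidean pointer distance.
    """
    centers = np.asarray(stroke_centers, dtype=np.float64)
    if centers.ndim != 2 or centers.shape[0] == 0:
        raise ValueError("stroke_centers must be a non-empty list of 3-D points")
    w = np.asarray(spacing, dtype=np.float64) / float(spacing[0])
    x = np.asarray(x, dtype=np.float64)
    diff = (x[..., None, :] - centers) * w
    return np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=-1)


def _dissimilarity_field(features: FeatureVolume, edit: EditOperation) -> np.ndarray:
    i, j, k = edit.x0
    if edit.metric == "orientation":
        e0 = features.e3[i, j, k]
        if not np.any(e0):
            log.warning(
                "reference point %s has no defined orientation (suppressed e3'); "
                "d_F = 1 everywhere",
                edit.x0,
            )
        return dissim_orientation(features.e3, e0)
    if edit.metric == "lambda_ratio":
        return dissim_lambda_ratio(
            features.lambda_ratio, features.lambda_ratio[i, j, k], features.sigma_lambda
        )
    stack = features.channel_stack()
    c0 = features.feature_at(edit.x0)
    if edit.channels is not None and edit.channels != features.channel_names:
        raise ValueError(
            f"edit channels {edit.channels} do not match feature volume "
            f"channels {features.channel_names}"
        )
    if edit.metric == "mahalanobis":
        return dissim_mahalanobis(stack, c0, features.covariance)
    # dot: Eq. for d_dot presumes unit feature vectors; normalise first.
    norms = np.linalg.norm(stack, axis=-1, keepdims=True)
    unit = np.divide(stack, norms, out=np.zeros_like(stack), where=norms > 0)
    n0 = np.linalg.norm(c0)
    u0 = c0 / n0 if n0 > 0 else c0
    if n0 == 0:
        log.warning("reference feature vector is zero under the dot metric")
    else:
        log.debug("dot metric: feature vectors normalised to unit length")
    return dissim_dot(unit, u0)


def compute_shift_field(
    vol: ScalarVolume, features: FeatureVolume, edit: EditOperation
) -> ShiftField:
    """Evaluate Delta(x) = (I(x0) - I(x)) * f_F(d_F) * f_E(d_E) everywhere."""
    if vol.shape != features.shape:
        raise ValueError("volume and feature volume grids differ")
    edit.validate_bounds(vol.shape)
    d_F = _dissimilarity_field(features, edit)
    grid = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float64) for n in vol.shape), indexing="ij"),
        axis=-1,
    )
    d_E = roi_distance(grid, edit.stroke_centers, vol.spacing)
    I0 = vol.data[edit.x0]
    delta = (I0 - vol.data) * f_F(d_F, edit.alpha) * f_E(d_E, edit.beta)
    return ShiftField(delta, vol.spacing, (edit,))


def combine_shift_fields(
    fields: Sequence[ShiftField],
    shape: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ShiftField:
    """Voxelwise sum of saved edits (order-independent); empty -> zero field.

    Clamping happens only at TF evaluation, so each edit keeps its local
    identity-at-equal-intensity property.  An empty list needs an explicit
    ``shape`` for the zero field.
    """
    fields = list(fields)
    if not fields:
        if shape is None:
            raise ValueError("an empty edit list needs an explicit grid shape")
        return ShiftField(np.zeros(shape), spacing, ())
    shape = fields[0].shape
    for f in fields[1:]:
        if f.shape != shape:
            raise ValueError(f"grid mismatch: {f.shape} vs {shape}")
    delta = np.sum([f.delta for f in fields], axis=0)
    prov = tuple(e for f in fields for e in f.provenance)
    return ShiftField(delta, fields[0].spacing, prov)


def zero_shift_field(vol: ScalarVolume) -> ShiftField:
    return ShiftField(np.zeros(vol.shape), vol.spacing, ())


def evaluate_shifted_tf(
    tf: TransferFunction1D,
    intensity: np.ndarray,
    delta: np.ndarray | float = 0.0,
    intensity_domain: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """RGBA of the shifted lookup TF_preset(clamp(I + Delta)).

    Delta = 0 reduces exactly to the preset.
    """
    shifted = np.clip(
        np.asarray(intensity, dtype=np.float64) + delta,
        intensity_domain[0],
        intensity_domain[1],
    )
    return tf(shifted)
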