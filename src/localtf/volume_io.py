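"""3-D scalar volume containers, file I/O and preprocessing.

Volumes are stored as ``(nx, ny, nz)`` float arrays indexed ``[x, y, z]``
(0-based voxel indices); the world position of a voxel is ``index * spacing``
in micrometres.  Multi-page TIFF stacks (page axis = z) and NRRD files with
per-axis spacings are supported.  NRRD support is a small built-in
reader/writer restricted to 3-D raw little-endian files, which is all the
pipeline persists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "TransferFunction1D",
    "read_volume",
    "write_volume",
    "median_filter",
    "normalize_intensity",
]


@dataclass(frozen=True)
class ScalarVolume:
    """A scalar intensity field I(x) on a regular anisotropic grid.

    Parameters
    ----------
    data
        ``(nx, ny, nz)`` array of intensities, indexed ``[x, y, z]``.
    spacing
        Physical step per axis ``(sx, sy, sz)`` in micrometres.
    intensity_domain
        ``(I_min, I_max)`` of the representable intensity range.  After
        :func:`normalize_intensity` this is ``(0, 1)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {data.ndim}-D")
        if min(data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        lo, hi = (float(v) for v in self.intensity_domain)
        if not lo < hi:
            raise ValueError("intensity_domain must satisfy I_min < I_max")
        if data.size and (data.min() < lo or data.max() > hi):
            raise ValueError(
                f"data range [{data.min()}, {data.max()}] outside "
                f"intensity_domain ({lo}, {hi})"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "intensity_domain", (lo, hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=data)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tiff_stack", "nrrd"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff_stack"
    if suffix == ".nrrd":
        return "nrrd"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def read_volume(
    path: str | Path,
    format: str | None = None,
    spacing: Sequence[float] | None = None,
    intensity_domain: tuple[float, float] | None = None,
) -> ScalarVolume:
    """Read a 3-D volume from a multi-page TIFF or an NRRD file.

    ``spacing`` overrides file metadata; if neither is available it defaults
    to (1, 1, 1) um with a logged warning.  The intensity domain defaults to
    the natural range of the stored dtype (e.g. [0, 255] for uint8) or to
    the data range for float files.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "tiff_stack":
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF stack, got {arr.ndim}-D data")
        dtype = arr.dtype
        data = np.asarray(arr, dtype=np.float64).transpose(2, 1, 0)  # (z,y,x)->(x,y,z)
        file_spacing = None
    else:
        data, file_spacing, dtype = _read_nrrd(path)
    if spacing is not None:
        sp = tuple(float(s) for s in spacing)
    elif file_spacing is not None:
        sp = file_spacing
    else:
        log.warning("%s carries no spacing metadata; defaulting to (1, 1, 1) um", path.name)
        sp = (1.0, 1.0, 1.0)
    if intensity_domain is None:
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            intensity_domain = (float(info.min), float(info.max))
        else:
            lo = float(min(data.min(), 0.0))
            hi = float(max(data.max(), 1.0))
            intensity_domain = (lo, hi)
    return ScalarVolume(data, sp, intensity_domain)


def write_volume(vol: ScalarVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume (or a persisted shift field) to TIFF or NRRD.

    Data are stored as float32 TIFF pages (page axis = z) or as a raw
    little-endian float64 NRRD with per-axis ``spacings``; both round-trip
    through :func:`read_volume`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "tiff_stack":
            pages = np.ascontiguousarray(vol.data.transpose(2, 1, 0), dtype=np.float32)
            tifffile.imwrite(path, pages, photometric="minisblack")
        else:
            _write_nrrd(vol, path)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Minimal NRRD (3-D, raw little-endian) support
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "float": np.float32,
    "double": np.float64,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "ushort": np.uint16,
    "unsigned short": np.uint16,
    "short": np.int16,
    "int": np.int32,
    "uint": np.uint32,
}


def _read_nrrd(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise IOError(f"{path} is not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n"):
                break
            if not line:
                raise IOError(f"unexpected end of NRRD header in {path}")
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, value = text.split(":", 1)
            header[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()
    if int(header.get("dimension", 0)) != 3:
        raise ValueError(f"expected 3-D NRRD, got dimension {header.get('dimension')}")
    if header.get("encoding", "raw") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    dtype = _NRRD_TYPES.get(header.get("type", "double"))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {header.get('type')!r}")
    sizes = tuple(int(v) for v in header["sizes"].split())
    endian = header.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    arr = np.frombuffer(payload, dtype=dt, count=int(np.prod(sizes)))
    # NRRD lists axes fastest-first; our x axis is the fastest.
    data = arr.reshape(sizes, order="F").astype(np.float64)
    spacing = None
    if "spacings" in header:
        spacing = tuple(float(v) for v in header["spacings"].split())
    return data, spacing, np.dtype(dtype)


def _write_nrrd(vol: ScalarVolume, path: Path) -> None:
    header = (
        "NRRD0004\n"
        "# stored by localtf\n"
        "type: double\n"
        "dimension: 3\n"
        f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"spacings: {vol.spacing[0]} {vol.spacing[1]} {vol.spacing[2]}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asarray(vol.data, dtype="<f8").tobytes(order="F"))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def median_filter(vol: ScalarVolume, radius: int = 1) -> ScalarVolume:
    """Denoise with a cubic median filter of half-width ``radius`` voxels.

    Each output voxel is the median of its (2r+1)^3 neighbourhood with edge
    replication; radius 0 is the identity.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return vol
    filtered = ndimage.median_filter(vol.data, size=2 * radius + 1, mode="nearest")
    return vol.with_data(filtered)


def normalize_intensity(vol: ScalarVolume) -> ScalarVolume:
    """Affinely rescale intensities to [0, 1] and reset the domain to (0, 1)."""
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant volume")
    data = (vol.data - lo) / (hi - lo)
    return ScalarVolume(data, vol.spacing, (0.0, 1.0))


# ---------------------------------------------------------------------------
# 1-D transfer-function presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFunction1D:
    """Piecewise-linear 1-D intensity -> RGBA preset (TF_preset).

    ``control_points`` is an ordered list of ``(intensity, (r, g, b, a))``
    with strictly increasing intensities and components in [0, 1].  Queries
    outside the covered range clamp to the nearest endpoint.
    """

    control_points: tuple[tuple[float, tuple[float, float, float, float]], ...]
    _grid: np.ndarray = field(init=False, repr=False, compare=False)
    _rgba: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = tuple(
            (float(i), tuple(float(c) for c in rgba)) for i, rgba in self.control_points
        )
        if len(pts) < 2:
            raise ValueError("a transfer function needs at least 2 control points")
        grid = np.array([p[0] for p in pts])
        rgba = np.array([p[1] for p in pts])
        if np.any(np.diff(grid) <= 0):
            raise ValueError("control-point intensities must be strictly increasing")
        if rgba.shape[1] != 4 or rgba.min() < 0 or rgba.max() > 1:
            raise ValueError("RGBA components must lie in [0, 1]")
        object.__setattr__(self, "control_points", pts)
        object.__setattr__(self, "_grid", grid)
        object.__setattr__(self, "_rgba", rgba)

    def __call__(self, intensity: np.ndarray | float) -> np.ndarray:
        """Evaluate the preset; returns ``(..., 4)`` RGBA in [0, 1]."""
        x = np.asarray(intensity, dtype=np.float64)
        out = np.empty(x.shape + (4,))
        for c in range(4):
            out[..., c] = np.interp(x, self._grid, self._rgba[:, c])
        return out

    def opacity(self, intensity: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(intensity, dtype=np.float64), self._grid, self._rgba[:, 3])

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = [
            {"intensity": i, "rgba": list(rgba)} for i, rgba in self.control_points
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TransferFunction1D":
        payload = json.loads(Path(path).read_text())
        return cls(tuple((p["intensity"], tuple(p["rgba"])) for p in payload))

    @classmethod
    def grayscale_ramp(
        cls, threshold: float = 0.2, full: float = 0.9, max_alpha: float = 1.0
    ) -> "TransferFunction1D":
        """White ramp: transparent below ``threshold``, opaque above ``full``."""
        return cls(
            (
                (0.0, (0.0, 0.0, 0.0, 0.0)),
                (threshold, (0.0, 0.0, 0.0, 0.0)),
                (full, (1.0, 1.0, 1.0, max_alpha)),
                (1.0, (1.0, 1.0, 1.0, max_alpha)),
            )
        )
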