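"""Replayable edit sessions.

A session config is a plain mapping (usually loaded from YAML) that scripts
the interactive loop: load a volume, median-filter and normalise it, build
the feature volume, apply an ordered list of edits, render, and persist the
image and the combined shift field.  Re-running the same config reproduces
every output bit for bit, and every defaulted parameter is logged so runs
are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import volume_io
from .features import DEFAULT_CHANNELS, FeatureVolume, build_feature_volume
from .render import RenderSettings, render, save_png
from .shift import EditOperation, ShiftField, combine_shift_fields, compute_shift_field
from .volume_io import ScalarVolume, TransferFunction1D

log = logging.getLogger(__name__)

__all__ = ["SessionConfig", "SessionResult", "run_session", "load_config"]


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to replay one visualization session."""

    input: str
    spacing: tuple[float, float, float] | None = None
    median_radius: int = 1
    normalize: bool = True
    feature_scale: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    tf_preset: str | None = None
    edits: tuple[EditOperation, ...] = ()
    render: RenderSettings = field(default_factory=RenderSettings)
    image_out: str | None = None
    shift_out: str | None = None

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], base: Path | None = None) -> "SessionConfig":
        base = base or Path.cwd()

        def _resolve(p):
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        edits = tuple(
            EditOperation(
                x0=tuple(e["x0"]),
                stroke_centers=tuple(tuple(c) for c in e["stroke_centers"]),
                alpha=float(e.get("alpha", 10.0)),
                beta=float(e.get("beta", 6.0)),
                metric=e.get("metric", "orientation"),
                channels=tuple(e["channels"]) if "channels" in e else None,
            )
            for e in raw.get("edits", [])
        )
        rs = raw.get("render", {})
        settings = RenderSettings(
            eye_direction=tuple(rs.get("eye_direction", (0.0, 0.0, -1.0))),
            image_size=tuple(rs["image_size"]) if rs.get("image_size") else None,
            step=float(rs.get("step", 0.5)),
            reference_step=float(rs.get("reference_step", 1.0)),
            background=tuple(rs.get("background", (0.0, 0.0, 0.0, 1.0))),
            early_termination_alpha=float(rs.get("early_termination_alpha", 0.99)),
        )
        outputs = raw.get("outputs", {})
        return cls(
            input=_resolve(raw["input"]),
            spacing=tuple(raw["spacing"]) if raw.get("spacing") else None,
            median_radius=int(raw.get("median_radius", 1)),
            normalize=bool(raw.get("normalize", True)),
            feature_scale=float(raw.get("feature_scale", 1.0)),
            channels=tuple(raw.get("channels", DEFAULT_CHANNELS)),
            tf_preset=_resolve(raw.get("tf_preset")),
            edits=edits,
            render=settings,
            image_out=_resolve(outputs.get("image")),
            shift_out=_resolve(outputs.get("shift")),
        )


def load_config(path: str | Path) -> SessionConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return SessionConfig.from_mapping(raw, base=path.parent)


@dataclass(frozen=True)
class SessionResult:
    volume: ScalarVolume
    features: FeatureVolume | None
    shift: ShiftField
    image: Any  # (H, W, 4) ndarray
    tf: TransferFunction1D


def run_session(config: SessionConfig) -> SessionResult:
    """Execute read -> filter -> normalize -> features -> shifts -> render."""
    vol = volume_io.read_volume(config.input, spacing=config.spacing)
    log.info("loaded %s: shape=%s spacing=%s", config.input, vol.shape, vol.spacing)
    if config.median_radius > 0:
        vol = volume_io.median_filter(vol, config.median_radius)
        log.info("median filter radius=%d", config.median_radius)
    if config.normalize:
        vol = volume_io.normalize_intensity(vol)
        log.info("intensities normalized to [0, 1]")

    if config.tf_preset:
        tf = TransferFunction1D.load(config.tf_preset)
    else:
        tf = TransferFunction1D.grayscale_ramp()
        log.info("no TF preset given; using the default grayscale ramp")

    for edit in config.edits:
        edit.validate_bounds(vol.shape)

    features = None
    if config.edits:
        features = build_feature_volume(vol, config.feature_scale, config.channels)
        log.info(
            "features: scale=%g channels=%s sigma_lambda=%g",
            config.feature_scale,
            features.channel_names,
            features.sigma_lambda,
        )
        fields = [compute_shift_field(vol, features, e) for e in config.edits]
        shift = combine_shift_fields(fields)
        for e in config.edits:
            log.info(
                "edit: x0=%s metric=%s alpha=%g beta=%g strokes=%d",
                e.x0, e.metric, e.alpha, e.beta, len(e.stroke_centers),
            )
    else:
        shift = combine_shift_fields([], shape=vol.shape, spacing=vol.spacing)

    log.info(
        "render: eye=%s step=%g reference_step=%g early_termination=%g",
        config.render.eye_direction,
        config.render.step,
        config.render.reference_step,
        config.render.early_termination_alpha,
    )
    image = render(vol, shift, tf, config.render)

    if config.image_out:
        save_png(image, config.image_out)
        log.info("wrote image %s", config.image_out)
    if config.shift_out:
        volume_io.write_volume(shift.as_volume(), config.shift_out)
        log.info("wrote shift field %s", config.shift_out)
    return SessionResult(vol, features, shift, image, tf)
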