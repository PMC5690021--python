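"""Matching configuration and config-file loading.

Defaults follow the clinically tuned operating point of the method:
``sn=0.8``, ``s_sigma=0.4``, ``M=40``, ``mt=30000``, ``s=480`` and
0.446 mm/px.  Intensities are treated on a 16-bit scale so that the masking
threshold ``mt=30000`` is meaningful; 8-bit inputs are rescaled by 257 on
load (see :mod:`setuperr.io`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Sequence

import yaml

from .types import ConfigError

__all__ = ["MatchConfig", "DEFAULT_PALETTE", "load_config"]

# 16-bit RGB palette used for rendered annotations (PTV contour, axes,
# grid marks, pointing marks).  Matches the synthetic generator's palette.
DEFAULT_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 65535.0),        # PTV contour
    (65535.0, 33410.0, 0.0),    # x/y axes
    (0.0, 54998.0, 0.0),        # grid marks
    (65535.0, 0.0, 0.0),        # pointing marks / numbers
)


@dataclass(frozen=True)
class MatchConfig:
    """Tunable parameters of the matching method.

    Parameters
    ----------
    s:
        Captured-image side length in pixels (480 in the original setting).
    sn:
        Calculation-window fraction in (0, 1]; the correlation window is
        ``N = round(s * sn)`` pixels on a side, centered on the isocenter.
    s_sigma:
        Gaussian-weight width as a fraction of N: ``sigma = N * s_sigma``.
    M:
        Search-window side in pixels; integer candidate offsets span the
        centered grid ``[-M//2, M - M//2 - 1]`` per axis.
    mt:
        Sobel-magnitude threshold for collimator (field-edge) masking, on
        the 16-bit intensity scale.
    subpixel_step_px:
        Pitch of the fractional refinement grid within +/-1 px of the
        integer correlation peak.
    pixel_spacing_mm:
        mm per pixel of the captured images.
    min_valid_px:
        Minimum number of unmasked in-bounds window pixels for a candidate
        offset to yield a defined correlation.
    bit_depth:
        Bit depth inputs are normalised to (8-bit files are scaled up by
        257 on load so mt keeps its 16-bit meaning).
    overlay_palette / palette_tolerance:
        Annotation colors to detect, with per-channel tolerance.
    """

    s: int = 480
    sn: float = 0.8
    s_sigma: float = 0.4
    M: int = 40
    mt: float = 30000.0
    subpixel_step_px: float = 0.05
    pixel_spacing_mm: float = 0.446
    min_valid_px: int = 16
    bit_depth: int = 16
    overlay_palette: tuple[tuple[float, float, float], ...] = DEFAULT_PALETTE
    palette_tolerance: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.sn <= 1:
            raise ConfigError("sn must lie in (0, 1]")
        if self.s_sigma <= 0:
            raise ConfigError("s_sigma must be > 0")
        if self.M < 1:
            raise ConfigError("M must be >= 1")
        if self.N < 3:
            raise ConfigError(f"window N=round(s*sn)={self.N} is too small (< 3)")
        if not 0 < self.subpixel_step_px <= 1:
            raise ConfigError("subpixel_step_px must lie in (0, 1]")
        if self.pixel_spacing_mm <= 0:
            raise ConfigError("pixel_spacing_mm must be > 0")
        if self.mt <= 0:
            raise ConfigError("mt must be > 0")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")

    @property
    def N(self) -> int:
        """Correlation-window side in pixels."""
        return int(round(self.s * self.sn))

    @property
    def sigma_px(self) -> float:
        """Gaussian-weight sigma in pixels, sigma = N * s_sigma."""
        return self.N * self.s_sigma

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["overlay_palette"] = [list(c) for c in self.overlay_palette]
        return d


def _coerce(raw: dict[str, Any]) -> MatchConfig:
    known = {f for f in MatchConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "overlay_palette" in raw:
        raw["overlay_palette"] = tuple(tuple(float(v) for v in c) for c in raw["overlay_palette"])
    try:
        return MatchConfig(**raw)
    except TypeError as exc:  # wrong value shapes
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None, **overrides: Any) -> MatchConfig:
    """Load a YAML/JSON config file, applying keyword overrides on top.

    Precedence: explicit overrides > file values > built-in defaults.
    ``path=None`` returns the defaults (plus overrides).
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            data = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        raw.update(data)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return _coerce(raw)
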