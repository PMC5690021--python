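"""Core in-memory containers shared across the pipeline.

Coordinate convention (fixed for the whole package): pixel indices are
0-based, ``(x, y) = (column, row)`` with the origin at the top-left corner.
All millimetre quantities are derived from pixel quantities only through
``pixel_spacing_mm``.

Sign convention: a reported displacement is "DRR position minus DR
position", i.e. the offset applied to the reference (DRR) so that it best
overlays the acquired image (DR).  A couch correction therefore equals the
negated report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

View = Literal["frontal", "lateral"]

__all__ = [
    "View",
    "Radiograph",
    "CapturedImage",
    "Displacement",
    "ReferenceDisplacement",
    "ConfigError",
    "ImageIOError",
    "MatchError",
]


class ConfigError(ValueError):
    """Invalid or unparsable configuration."""


class ImageIOError(OSError):
    """Unreadable or malformed image input."""


class MatchError(RuntimeError):
    """Block matching could not produce a defined correlation anywhere."""


def _check_grid(pixels: np.ndarray, ndim: tuple[int, ...]) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim not in ndim or arr.size == 0:
        raise ValueError(f"expected a non-empty grid with ndim in {ndim}, got shape {arr.shape}")
    return arr


@dataclass
class Radiograph:
    """A single-channel 2D radiograph with its geometric metadata.

    Parameters
    ----------
    pixels:
        2D array of non-negative intensities (16-bit scale, stored float64).
    view:
        ``"frontal"`` or ``"lateral"``.
    pixel_spacing_mm:
        Isotropic pixel spacing, mm per pixel, > 0.
    isocenter_px:
        Planned isocenter position ``(x, y)`` in pixel coordinates; must lie
        inside the grid.
    """

    pixels: np.ndarray
    view: View
    pixel_spacing_mm: float
    isocenter_px: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = _check_grid(self.pixels, (2,))
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        x, y = self.isocenter_px
        h, w = self.pixels.shape
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"isocenter {self.isocenter_px} outside {w}x{h} grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class CapturedImage:
    """A captured screen image: grayscale radiograph or RGB with overlays.

    ``pixels`` is ``(H, W)`` for grayscale or ``(H, W, 3)`` for color.
    Colored pixels are annotation overlays (PTV contour, axes, grid marks,
    pointing marks) to be detected and inpainted before matching.
    """

    pixels: np.ndarray
    view: View
    pixel_spacing_mm: float
    isocenter_px: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = _check_grid(self.pixels, (2, 3))
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color images must have exactly 3 channels")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        x, y = self.isocenter_px
        h, w = self.pixels.shape[:2]
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"isocenter {self.isocenter_px} outside {w}x{h} grid")

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    def to_gray(self) -> np.ndarray:
        """Channel mean for color input; identity for grayscale."""
        if self.pixels.ndim == 2:
            return self.pixels.copy()
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class Displacement:
    """Best-match offset of the DRR relative to the DR, in pixels.

    ``dx_px``/``dy_px`` may be fractional after subpixel refinement.
    ``peak_correlation`` is the weighted ZNCC value at the returned offset.
    """

    dx_px: float
    dy_px: float
    peak_correlation: float
    view: View
    n_valid_px: int = 0
    at_search_border: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.peak_correlation <= 1.0 + 1e-9:
            raise ValueError("peak_correlation outside [-1, 1]")

    def to_mm(self, pixel_spacing_mm: float) -> tuple[float, float]:
        return self.dx_px * pixel_spacing_mm, self.dy_px * pixel_spacing_mm


@dataclass(frozen=True)
class ReferenceDisplacement:
    """A frontal/lateral displacement pair (one registration of both views)."""

    frontal: Displacement
    lateral: Displacement

    def __post_init__(self) -> None:
        if self.frontal.view != "frontal" or self.lateral.view != "lateral":
            raise ValueError("displacement views must be (frontal, lateral)")
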