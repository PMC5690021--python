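"""Captured-image preprocessing: overlay inpainting and collimator masking.

Captured positioning screens carry rendered annotations (PTV contour, x/y
axes, grid marks, pointing marks and numbers) on top of the radiograph, and
the DR contains a region blocked by the beam collimators that carries no
anatomy.  Matching must see neither.  The steps here are:

1. detect annotation pixels by color against a configurable palette;
2. replace them by iterated 8-neighborhood averaging ("onion-peel");
3. locate the collimated border via a Sobel gradient-magnitude threshold
   ``mt``, scanning each row left/right and each column top/bottom for the
   first field-edge point, and blocking everything outside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import MatchConfig
from .types import CapturedImage, Radiograph

__all__ = [
    "detect_overlay_mask",
    "inpaint_overlay",
    "sobel_magnitude",
    "detect_collimator_mask",
    "preprocess_captured",
    "PreprocessResult",
]

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def detect_overlay_mask(
    image: CapturedImage,
    palette: Sequence[Sequence[float]],
    tolerance: float | Sequence[float] = 0.0,
) -> np.ndarray:
    """Boolean mask of pixels whose color matches any palette entry.

    A pixel matches a palette color when every channel differs by at most
    the (per-channel) ``tolerance``.  Grayscale input cannot be
    color-matched and raises ``ValueError``.
    """
    if len(palette) == 0:
        raise ValueError("palette must be non-empty")
    if image.channels != 3:
        raise ValueError("overlay detection needs a 3-channel (color) image")
    tol = np.broadcast_to(np.asarray(tolerance, dtype=np.float64), (3,))
    mask = np.zeros(image.pixels.shape[:2], dtype=bool)
    for color in palette:
        c = np.asarray(color, dtype=np.float64)
        if c.shape != (3,):
            raise ValueError("palette entries must be RGB triples")
        mask |= (np.abs(image.pixels - c) <= tol).all(axis=2)
    return mask


def inpaint_overlay(pixels: np.ndarray, overlay: np.ndarray) -> np.ndarray:
    """Fill overlay pixels with the mean of their non-overlay 8-neighbors.

    Pixels whose whole 8-neighborhood is overlay are filled on later passes
    from already-filled neighbors, so arbitrarily thick annotations peel
    inward deterministically.  Non-overlay pixels are returned bit-exact.

    Accepts a 2D grid or an (H, W, 3) color grid (channels filled
    independently under the shared mask).
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    overlay = np.asarray(overlay, dtype=bool)
    if overlay.shape != pixels.shape[:2]:
        raise ValueError("overlay mask shape must match the image grid")
    if overlay.all():
        raise ValueError("overlay covers the entire image; nothing to interpolate from")
    if pixels.ndim == 3:
        out = pixels.copy()
        for ch in range(pixels.shape[2]):
            out[:, :, ch] = inpaint_overlay(pixels[:, :, ch], overlay)
        return out

    out = pixels.copy()
    remaining = overlay.copy()
    while remaining.any():
        valid = ~remaining
        counts = ndimage.correlate(valid.astype(np.float64), _NEIGHBOR_KERNEL, mode="constant")
        sums = ndimage.correlate(np.where(valid, out, 0.0), _NEIGHBOR_KERNEL, mode="constant")
        fill = remaining & (counts > 0)
        if not fill.any():  # isolated all-overlay components cannot occur once ~overlay is non-empty
            raise ValueError("overlay region is not reachable from any valid pixel")
        out[fill] = sums[fill] / counts[fill]
        remaining &= ~fill
    return out


def sobel_magnitude(pixels: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the pair of 3x3 Sobel kernels.

    Horizontal and vertical responses are combined in quadrature; image
    borders are handled by edge replication, so a constant image yields an
    exactly zero magnitude everywhere.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("sobel_magnitude expects a single-channel image")
    if min(pixels.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gy = ndimage.sobel(pixels, axis=0, mode="nearest")
    gx = ndimage.sobel(pixels, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def detect_collimator_mask(edges: np.ndarray, mt: float) -> np.ndarray:
    """Blocked-region mask from a gradient-magnitude grid.

    Each row is scanned inward from the left and from the right; pixels up
    to and including the first point with magnitude > ``mt`` are blocked.
    Columns are scanned the same way top/bottom, and the final mask is the
    union of the row-wise and column-wise blocked sets.  Rows or columns
    with no supra-threshold point contribute no blocked pixels: the
    collimated region always terminates in a high-contrast field edge, so
    an edge-free line is treated as fully usable.
    """
    if mt <= 0:
        raise ValueError("mt must be > 0")
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 2:
        raise ValueError("edge grid must be 2D")
    mask = _scan_rows(edges > mt)
    mask |= _scan_rows((edges > mt).T).T
    return mask


def _scan_rows(hits: np.ndarray) -> np.ndarray:
    """Row-wise blocked set: everything outside the first hit from each end."""
    n_rows, n_cols = hits.shape
    mask = np.zeros_like(hits, dtype=bool)
    any_hit = hits.any(axis=1)
    first = hits.argmax(axis=1)
    last = n_cols - 1 - hits[:, ::-1].argmax(axis=1)
    cols = np.arange(n_cols)
    mask[any_hit] = (cols <= first[any_hit, None]) | (cols >= last[any_hit, None])
    return mask


@dataclass
class PreprocessResult:
    """Cleaned radiograph plus the masks the cleaning was based on."""

    radiograph: Radiograph
    overlay_mask: np.ndarray
    blocked_mask: np.ndarray

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.blocked_mask


def preprocess_captured(image: CapturedImage, cfg: MatchConfig) -> PreprocessResult:
    """Full preprocessing chain on one captured image.

    Color input: detect annotation pixels against ``cfg.overlay_palette``,
    inpaint them, collapse to one channel.  Then Sobel + field-edge scan
    produce the collimator mask.  Grayscale input skips the overlay steps.
    """
    if image.channels == 3:
        overlay = detect_overlay_mask(image, cfg.overlay_palette, cfg.palette_tolerance)
        gray = inpaint_overlay(image.pixels, overlay).mean(axis=2)
    else:
        overlay = np.zeros(image.pixels.shape, dtype=bool)
        gray = image.pixels.copy()
    blocked = detect_collimator_mask(sobel_magnitude(gray), cfg.mt)
    rad = Radiograph(
        pixels=gray,
        view=image.view,
        pixel_spacing_mm=image.pixel_spacing_mm,
        isocenter_px=image.isocenter_px,
    )
    return PreprocessResult(radiograph=rad, overlay_mask=overlay, blocked_mask=blocked)
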