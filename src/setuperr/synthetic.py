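"""Synthetic pelvic-phantom DR/DRR pairs with exact ground truth.

The generator emulates the inputs of the couch-movement accuracy
experiment: a bone-like reference projection per view (the "DRR"), and an
acquired image (the "DR") that is the reference rigidly translated by a
known couch displacement, with an intensity gain/offset drift, additive
Gaussian sensor noise, collimator-blocked borders ending in a sharp field
edge, and colored screen annotations (PTV contour, axes, grid marks,
pointing marks) painted on top.

The phantom is procedural — soft-edged ellipses and bars over a graded,
band-limited textured background — not a CT projection; the matcher is
agnostic to anatomical realism, and the texture gives the correlation
surface a sharp, well-conditioned peak.  The lateral view is rendered at
reduced contrast, mirroring the longer lateral transmission path of real
orthogonal setups.

All randomness flows from a single integer seed; every output is
bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DEFAULT_PALETTE
from .geometry import CouchShift
from .types import CapturedImage, Radiograph, View

__all__ = [
    "BoneFeature",
    "PhantomSpec",
    "GroundTruth",
    "render_drr",
    "render_dr",
    "couch_pattern",
    "simulate_pointing",
    "default_bone_features",
]


@dataclass(frozen=True)
class BoneFeature:
    """One soft-edged bright structure: an ellipse, ring or bar."""

    kind: str                 # "ellipse" | "ring" | "bar"
    center: tuple[float, float]   # (x, y), fractions of the image side
    axes: tuple[float, float]     # semi-axes, fractions of the image side
    intensity: float              # added intensity, 16-bit counts
    softness_px: float = 3.0      # Gaussian edge softening


def default_bone_features() -> tuple[BoneFeature, ...]:
    """Pelvis-like scene: iliac ring, two femoral heads, sacral bar."""
    return (
        BoneFeature("ring", (0.50, 0.44), (0.26, 0.20), 15000.0, 3.0),
        BoneFeature("ellipse", (0.30, 0.62), (0.075, 0.075), 12000.0, 2.5),
        BoneFeature("ellipse", (0.70, 0.62), (0.075, 0.075), 12000.0, 2.5),
        BoneFeature("bar", (0.50, 0.50), (0.055, 0.28), 9000.0, 3.0),
        BoneFeature("ellipse", (0.50, 0.71), (0.16, 0.065), 8000.0, 3.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that defines one synthetic acquisition.

    Intensity parameters are on the 16-bit scale.  ``noise_sd`` is the
    additive Gaussian sensor-noise SD of the DR; ``contrast_gain`` /
    ``contrast_offset`` model the DR/DRR intensity drift;
    ``lateral_contrast`` scales structure contrast in the lateral view;
    ``collimation_margins_px`` are the blocked widths (left, right, top,
    bottom) of the DR.  Defaults are the study conditions used throughout
    the tests and the accuracy experiment.
    """

    size_px: int = 480
    pixel_spacing_mm: float = 0.446
    bone_features: tuple[BoneFeature, ...] = field(default_factory=default_bone_features)
    background_level: float = 16000.0
    background_slope: float = 4000.0
    texture_sd: float = 1500.0
    texture_scale_px: float = 4.0
    noise_sd: float = 800.0
    contrast_gain: float = 0.92
    contrast_offset: float = 1500.0
    lateral_contrast: float = 0.55
    collimation_margins_px: tuple[int, int, int, int] = (40, 40, 40, 40)
    overlay: bool = True
    overlay_palette: tuple[tuple[float, float, float], ...] = DEFAULT_PALETTE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 64:
            raise ValueError("size_px must be >= 64")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def isocenter_px(self) -> tuple[float, float]:
        c = (self.size_px - 1) / 2.0
        return (c, c)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one rendered DR."""

    applied_shift: CouchShift
    # content translation of the DR relative to the DRR, pixels, (dx, dy)
    frontal_offset_px: tuple[float, float]
    lateral_offset_px: tuple[float, float]
    # the displacement the matcher should report for this view (= -content shift)
    expected_dx_px: float
    expected_dy_px: float
    view: View
    pixel_spacing_mm: float
    overlay_mask: np.ndarray | None
    blocked_mask: np.ndarray


def _view_content_shift(shift: CouchShift, view: View, spacing: float) -> tuple[float, float]:
    """Pixel content translation of the DR for a given couch movement.

    Positive couch movement produces a positive image-content displacement
    of equal magnitude along the mapped axis: frontal x <- lateral couch
    axis, lateral x <- vertical couch axis, both y <- longitudinal.
    """
    if view == "frontal":
        return shift.lat_mm / spacing, shift.long_mm / spacing
    return shift.vert_mm / spacing, shift.long_mm / spacing


def render_drr(spec: PhantomSpec, view: View) -> Radiograph:
    """Deterministic bone-like reference projection for one view."""
    s = spec.size_px
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    img = spec.background_level + spec.background_slope * (0.5 * xx + 0.5 * yy) / s

    contrast = spec.lateral_contrast if view == "lateral" else 1.0
    for f in spec.bone_features:
        cx, cy = f.center[0] * s, f.center[1] * s
        ax, ay = max(f.axes[0] * s, 1.0), max(f.axes[1] * s, 1.0)
        if f.kind == "bar":
            inside = (np.abs(xx - cx) <= ax) & (np.abs(yy - cy) <= ay)
        else:
            r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
            if f.kind == "ring":
                inside = (r2 <= 1.0) & (r2 >= 0.55)
            else:
                inside = r2 <= 1.0
        soft = ndimage.gaussian_filter(inside.astype(np.float64), f.softness_px)
        img += contrast * f.intensity * soft

    if spec.texture_sd > 0:
        view_idx = 0 if view == "frontal" else 1
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, view_idx]))
        tex = ndimage.gaussian_filter(rng.standard_normal((s, s)), spec.texture_scale_px)
        tex *= spec.texture_sd / max(tex.std(), 1e-12)
        img += contrast * tex

    np.clip(img, 0.0, 60000.0, out=img)
    return Radiograph(
        pixels=img,
        view=view,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        isocenter_px=spec.isocenter_px,
    )


def _paint_overlays(
    gray: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """RGB captured frame with annotations painted; returns (rgb, overlay mask)."""
    s = spec.size_px
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    mask = np.zeros((s, s), dtype=bool)
    ptv, axes_c, grid_c, point_c = (np.asarray(c, dtype=np.float64) for c in spec.overlay_palette[:4])
    cx, cy = spec.isocenter_px
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # PTV contour: a thin ellipse around the isocenter
    r2 = ((xx - cx) / (0.18 * s)) ** 2 + ((yy - cy) / (0.15 * s)) ** 2
    m = np.abs(r2 - 1.0) < 0.035
    mask |= m
    rgb[m] = ptv

    # x / y axes through the isocenter, one pixel wide
    m = np.zeros_like(mask)
    m[int(round(cy)), :] = True
    m[:, int(round(cx))] = True
    mask |= m
    rgb[m] = axes_c

    # grid marks every 60 px (2 x 2 squares)
    for gy in range(30, s - 1, 60):
        for gx in range(30, s - 1, 60):
            m = np.zeros_like(mask)
            m[gy : gy + 2, gx : gx + 2] = True
            mask |= m
            rgb[m] = grid_c

    # pointing marks: small crosses at randomized bony-landmark-ish spots
    for _ in range(4):
        px = int(rng.integers(int(0.25 * s), int(0.75 * s)))
        py = int(rng.integers(int(0.25 * s), int(0.75 * s)))
        m = np.zeros_like(mask)
        m[py, max(px - 3, 0) : px + 4] = True
        m[max(py - 3, 0) : py + 4, px] = True
        mask |= m
        rgb[m] = point_c

    return rgb, mask


def render_dr(
    drr: Radiograph, shift: CouchShift, spec: PhantomSpec
) -> tuple[CapturedImage, GroundTruth]:
    """Acquired-image realization of the DRR under a known couch movement.

    The DR is the DRR translated by the view-mapped content shift (bilinear
    resampling for fractional shifts), passed through the gain/offset
    intensity drift, corrupted by additive Gaussian noise, zeroed in the
    collimated border bands, and — when ``spec.overlay`` is set — painted
    with palette-colored annotations on an RGB frame.
    """
    s = spec.size_px
    if drr.pixels.shape != (s, s):
        raise ValueError("DRR shape does not match the spec")
    tx, ty = _view_content_shift(shift, drr.view, spec.pixel_spacing_mm)
    ml, mr, mt_, mb = spec.collimation_margins_px
    usable_w = s - ml - mr - abs(tx)
    usable_h = s - mt_ - mb - abs(ty)
    if usable_w < 8 or usable_h < 8:
        raise ValueError("shift leaves no usable region inside the collimation")

    shifted = ndimage.shift(drr.pixels, (ty, tx), order=1, mode="nearest")
    label_key = zlib.crc32(shift.label.encode()) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 2 if drr.view == "frontal" else 3, label_key])
    )
    dr = shifted * spec.contrast_gain + spec.contrast_offset
    if spec.noise_sd > 0:
        dr = dr + rng.normal(0.0, spec.noise_sd, size=dr.shape)
    np.clip(dr, 0.0, 65535.0, out=dr)

    blocked = np.zeros((s, s), dtype=bool)
    if ml:
        blocked[:, :ml] = True
    if mr:
        blocked[:, s - mr :] = True
    if mt_:
        blocked[:mt_, :] = True
    if mb:
        blocked[s - mb :, :] = True
    dr[blocked] = 0.0

    overlay_mask: np.ndarray | None = None
    if spec.overlay:
        rgb, overlay_mask = _paint_overlays(dr, spec, rng)
        pixels = rgb
    else:
        pixels = dr

    captured = CapturedImage(
        pixels=pixels,
        view=drr.view,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        isocenter_px=spec.isocenter_px,
    )
    truth = GroundTruth(
        applied_shift=shift,
        frontal_offset_px=_view_content_shift(shift, "frontal", spec.pixel_spacing_mm),
        lateral_offset_px=_view_content_shift(shift, "lateral", spec.pixel_spacing_mm),
        expected_dx_px=-tx,
        expected_dy_px=-ty,
        view=drr.view,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        overlay_mask=overlay_mask,
        blocked_mask=blocked,
    )
    return captured, truth


_PATTERN_MM = (0.5, 1.0, 2.0, 4.0, 10.0, -0.5, -1.0, -2.0, -4.0, -10.0)


def couch_pattern() -> list[CouchShift]:
    """The 10-position evaluation pattern.

    Each magnitude (+/-0.5, 1, 2, 4, 10 mm) is applied simultaneously to
    the lateral, vertical and longitudinal couch axes.
    """
    return [CouchShift(m, m, m, label=str(i + 1)) for i, m in enumerate(_PATTERN_MM)]


def simulate_pointing(
    truth: GroundTruth,
    observer_sd_mm: float = 0.21,
    n_observers: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Manual-pointing stand-in: ground truth plus per-observer noise.

    Returns an ``(n_observers, 2)`` array of (dx_mm, dy_mm) estimates of
    the view's displacement, each the exact ground truth plus independent
    Gaussian observer noise (default SD 0.21 mm, the mean inter-observer
    variability of trained technicians on phantom images).
    """
    if observer_sd_mm < 0:
        raise ValueError("observer_sd_mm must be >= 0")
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    base_mm = np.array(
        [truth.expected_dx_px, truth.expected_dy_px], dtype=np.float64
    ) * truth.pixel_spacing_mm
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    noise = rng.normal(0.0, observer_sd_mm, size=(n_observers, 2))
    return base_mm[None, :] + noise
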