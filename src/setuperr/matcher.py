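"""Gaussian-weighted ZNCC block matching with subpixel refinement.

The residual setup error between a DR and its reference DRR is found by
maximising a weighted zero-mean normalized cross-correlation

    R(d) = sum_w (A' - mean A')(B' - mean B')
           / sqrt( sum_w (A' - mean A')^2 * sum_w (B' - mean B')^2 )

over candidate offsets d of the DRR, where the primed intensities are the
raw intensities multiplied by an isocenter-centered Gaussian weight

    w(p + d) = exp(-(|ic - p - d|^2) / (2 sigma^2)),   sigma = N * s_sigma,

evaluated at the displaced position (the weight field travels with the
candidate offset and multiplies both images, so importance concentrates on
anatomy near the planned isocenter).  Sums run over an N x N window
centered on the isocenter, excluding collimator-masked and out-of-bounds
pixels.  The integer argmax over the centered M x M search grid is refined
on a fractional grid (pitch ``subpixel_step_px``) within +/-1 px, sampling
the DRR at fractional offsets by bilinear interpolation.

Everything here is deterministic: no random numbers, stable tie-breaking
(smallest Euclidean offset, then row-major scan order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MatchConfig
from .types import Displacement, MatchError, Radiograph

__all__ = [
    "compute_sigma",
    "gaussian_weight",
    "weighted_zncc",
    "correlation_surface",
    "CorrelationSurface",
    "best_match",
]


def compute_sigma(N: int, s_sigma: float) -> float:
    """Gaussian-weight sigma in pixels: ``sigma = N * s_sigma``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if s_sigma <= 0:
        raise ValueError("s_sigma must be > 0")
    return N * s_sigma


def gaussian_weight(
    p: tuple[float, float] | np.ndarray,
    d: tuple[float, float],
    ic: tuple[float, float],
    sigma: float,
):
    """Isocenter-centered Gaussian weight at the displaced position p + d.

    ``p`` may be a single ``(x, y)`` pair or an array whose last axis is
    ``(x, y)``; the weight is ``exp(-(dx^2 + dy^2) / (2 sigma^2))`` with
    ``dx = x_ic - x - dx_offset`` etc., always in ``(0, 1]``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    p = np.asarray(p, dtype=np.float64)
    ddx = ic[0] - p[..., 0] - d[0]
    ddy = ic[1] - p[..., 1] - d[1]
    out = np.exp(-(ddx**2 + ddy**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# internal evaluation context


@dataclass
class _Context:
    """Precomputed quantities shared by every candidate offset."""

    dr_win: np.ndarray        # N x N DR window (fixed)
    drr_pad: np.ndarray       # DRR padded with NaN by `pad`
    valid_win: np.ndarray     # N x N usable-pixel mask of the DR window
    xs: np.ndarray            # window x coordinates (image frame)
    ys: np.ndarray            # window y coordinates
    ic: tuple[float, float]
    sigma: float
    x0: int
    y0: int
    pad: int
    N: int
    min_valid: int

    def weight(self, dx: float, dy: float) -> np.ndarray:
        """Separable Gaussian weight window at candidate offset (dx, dy)."""
        wx = np.exp(-((self.ic[0] - self.xs - dx) ** 2) / (2.0 * self.sigma**2))
        wy = np.exp(-((self.ic[1] - self.ys - dy) ** 2) / (2.0 * self.sigma**2))
        return np.outer(wy, wx)

    def drr_patch_int(self, dx: int, dy: int) -> np.ndarray:
        """DRR window displaced by an integer offset (NaN where out of bounds)."""
        r0 = self.y0 + dy + self.pad
        c0 = self.x0 + dx + self.pad
        return self.drr_pad[r0 : r0 + self.N, c0 : c0 + self.N]

    def drr_patch(self, dx: float, dy: float) -> np.ndarray:
        """DRR window at a possibly fractional offset (bilinear resampling)."""
        ix, iy = int(np.floor(dx)), int(np.floor(dy))
        fx, fy = dx - ix, dy - iy
        if fx == 0.0 and fy == 0.0:
            return self.drr_patch_int(ix, iy)
        p00 = self.drr_patch_int(ix, iy)
        p10 = self.drr_patch_int(ix + 1, iy)
        p01 = self.drr_patch_int(ix, iy + 1)
        p11 = self.drr_patch_int(ix + 1, iy + 1)
        return (
            (1 - fx) * (1 - fy) * p00
            + fx * (1 - fy) * p10
            + (1 - fx) * fy * p01
            + fx * fy * p11
        )

    def zncc(self, dx: float, dy: float) -> tuple[float, int]:
        """Weighted ZNCC at one candidate offset; (nan, n) when undefined."""
        patch = self.drr_patch(dx, dy)
        v = self.valid_win & np.isfinite(patch)
        n = int(v.sum())
        if n < self.min_valid:
            return float("nan"), n
        w = self.weight(dx, dy)
        a = np.where(v, patch * w, 0.0)
        b = np.where(v, self.dr_win * w, 0.0)
        sa = a.sum()
        sb = b.sum()
        af = a.ravel()
        bf = b.ravel()
        saa = af @ af
        sbb = bf @ bf
        sab = af @ bf
        var_a = saa - sa * sa / n
        var_b = sbb - sb * sb / n
        den = var_a * var_b
        if den <= 0.0:
            return float("nan"), n
        r = (sab - sa * sb / n) / np.sqrt(den)
        return float(np.clip(r, -1.0, 1.0)), n


def _make_context(
    dr: Radiograph,
    drr: Radiograph,
    valid: np.ndarray | None,
    cfg: MatchConfig,
) -> _Context:
    N = cfg.N
    ic = dr.isocenter_px
    x0 = int(round(ic[0])) - N // 2
    y0 = int(round(ic[1])) - N // 2
    h, w = dr.pixels.shape
    if x0 < 0 or y0 < 0 or x0 + N > w or y0 + N > h:
        raise MatchError(
            f"{N}x{N} window centered on isocenter {ic} does not fit a {w}x{h} image"
        )
    if valid is None:
        valid = np.ones_like(dr.pixels, dtype=bool)
    if valid.shape != dr.pixels.shape:
        raise ValueError("valid mask shape must match the DR")
    pad = cfg.M // 2 + 3
    drr_pad = np.pad(drr.pixels, pad, mode="constant", constant_values=np.nan)
    return _Context(
        dr_win=dr.pixels[y0 : y0 + N, x0 : x0 + N],
        drr_pad=drr_pad,
        valid_win=valid[y0 : y0 + N, x0 : x0 + N],
        xs=np.arange(x0, x0 + N, dtype=np.float64),
        ys=np.arange(y0, y0 + N, dtype=np.float64),
        ic=ic,
        sigma=compute_sigma(N, cfg.s_sigma),
        x0=x0,
        y0=y0,
        pad=pad,
        N=N,
        min_valid=cfg.min_valid_px,
    )


def weighted_zncc(
    dr: Radiograph,
    drr: Radiograph,
    d: tuple[float, float],
    cfg: MatchConfig,
    valid: np.ndarray | None = None,
) -> float:
    """Weighted ZNCC of the DRR displaced by ``d`` against the DR.

    Returns NaN (the "undefined correlation" sentinel) when fewer than
    ``cfg.min_valid_px`` usable pixels remain or either weighted patch has
    zero variance; callers must skip such candidates.
    """
    ctx = _make_context(dr, drr, valid, cfg)
    r, _ = ctx.zncc(float(d[0]), float(d[1]))
    return r


@dataclass
class CorrelationSurface:
    """R values over the centered M x M integer offset grid.

    ``values[j, i]`` is R at offset ``(dx_offsets[i], dy_offsets[j])``;
    undefined candidates are NaN.
    """

    values: np.ndarray
    dx_offsets: np.ndarray
    dy_offsets: np.ndarray

    def argmax(self) -> tuple[int, int, float]:
        """Offset of the surface maximum with deterministic tie-breaking.

        Ties on R are broken by the smallest Euclidean offset, then by
        row-major (dy, dx) scan order.
        """
        finite = np.isfinite(self.values)
        if not finite.any():
            raise MatchError("correlation undefined at every candidate offset")
        best_r = np.nanmax(self.values)
        js, iis = np.nonzero(finite & (self.values == best_r))
        dxs = self.dx_offsets[iis]
        dys = self.dy_offsets[js]
        order = np.lexsort((iis, js, dxs**2 + dys**2))
        k = order[0]
        return int(dxs[k]), int(dys[k]), float(best_r)


def _offsets(M: int) -> np.ndarray:
    return np.arange(-(M // 2), M - M // 2)


def correlation_surface(
    dr: Radiograph,
    drr: Radiograph,
    cfg: MatchConfig,
    valid: np.ndarray | None = None,
) -> CorrelationSurface:
    """Evaluate R at every integer offset of the centered M x M search grid."""
    ctx = _make_context(dr, drr, valid, cfg)
    offs = _offsets(cfg.M)
    values = np.full((offs.size, offs.size), np.nan)
    for j, dy in enumerate(offs):
        for i, dx in enumerate(offs):
            values[j, i], _ = ctx.zncc(float(dx), float(dy))
    surf = CorrelationSurface(values=values, dx_offsets=offs.copy(), dy_offsets=offs.copy())
    if not np.isfinite(values).any():
        raise MatchError("correlation undefined at every candidate offset")
    return surf


def best_match(
    dr: Radiograph,
    drr: Radiograph,
    cfg: MatchConfig,
    valid: np.ndarray | None = None,
) -> Displacement:
    """Best-matching DRR offset: integer argmax plus subpixel refinement.

    The refinement re-evaluates R on a fractional grid of pitch
    ``cfg.subpixel_step_px`` within +/-1 px of the integer peak, sampling
    the DRR bilinearly; since the grid contains the integer peak itself the
    refined R never falls below it.  Ties break toward the smallest
    Euclidean offset, then row-major order.
    """
    ctx = _make_context(dr, drr, valid, cfg)
    surf = correlation_surface(dr, drr, cfg, valid)
    dx0, dy0, r0 = surf.argmax()

    step = cfg.subpixel_step_px
    k = int(round(1.0 / step))
    best = (r0, float(dx0**2 + dy0**2), float(dx0), float(dy0))
    n_at_best = ctx.zncc(float(dx0), float(dy0))[1]
    for jj in range(-k, k + 1):
        dy = dy0 + jj * step
        for ii in range(-k, k + 1):
            if ii == 0 and jj == 0:
                continue
            dx = dx0 + ii * step
            r, n = ctx.zncc(dx, dy)
            if np.isnan(r):
                continue
            d2 = dx * dx + dy * dy
            if r > best[0] + 1e-15 or (abs(r - best[0]) <= 1e-15 and d2 < best[1] - 1e-12):
                best = (r, d2, dx, dy)
                n_at_best = n

    border = (
        dx0 <= surf.dx_offsets[0]
        or dx0 >= surf.dx_offsets[-1]
        or dy0 <= surf.dy_offsets[0]
        or dy0 >= surf.dy_offsets[-1]
    )
    return Displacement(
        dx_px=best[2],
        dy_px=best[3],
        peak_correlation=best[0],
        view=dr.view,
        n_valid_px=n_at_best,
        at_search_border=bool(border),
    )
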