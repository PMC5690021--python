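"""Independent brute-force oracles, written as literal loop transcriptions.

These deliberately share no code with the package: plain Python loops,
explicit bilinear interpolation, textbook formulas.  They are only run on
tiny inputs.
"""

import math

import numpy as np


def bilinear(img, x, y):
    """Sample img at fractional (x, y); None when out of bounds."""
    h, w = img.shape
    x0, y0 = math.floor(x), math.floor(y)
    if x0 < 0 or y0 < 0 or x0 + 1 > w - 1 or y0 + 1 > h - 1:
        if x0 == x and y0 == y and 0 <= x0 < w and 0 <= y0 < h:
            return img[y0, x0]
        return None
    fx, fy = x - x0, y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def zncc_oracle(dr, drr, d, ic, N, sigma, valid=None, min_valid=16):
    """Literal weighted-ZNCC transcription at one candidate offset.

    Window of side N centered on the (rounded) isocenter; the Gaussian
    weight is evaluated at the displaced position and multiplies both
    images; means are taken over the valid window pixels of the weighted
    values; masked or out-of-bounds pixels are excluded from every sum.
    """
    dx, dy = d
    icx, icy = ic
    x0 = round(icx) - N // 2
    y0 = round(icy) - N // 2
    a_vals, b_vals = [], []
    for y in range(y0, y0 + N):
        for x in range(x0, x0 + N):
            if valid is not None and not valid[y, x]:
                continue
            s = bilinear(drr, x + dx, y + dy)
            if s is None:
                continue
            w = math.exp(-((icx - x - dx) ** 2 + (icy - y - dy) ** 2) / (2 * sigma**2))
            a_vals.append(s * w)
            b_vals.append(dr[y, x] * w)
    n = len(a_vals)
    if n < min_valid:
        return float("nan")
    ma = sum(a_vals) / n
    mb = sum(b_vals) / n
    num = sum((a - ma) * (b - mb) for a, b in zip(a_vals, b_vals))
    da = sum((a - ma) ** 2 for a in a_vals)
    db = sum((b - mb) ** 2 for b in b_vals)
    if da <= 0 or db <= 0:
        return float("nan")
    return num / math.sqrt(da * db)


def exhaustive_best_match(dr, drr, ic, N, M, sigma, step, valid=None, min_valid=16):
    """Argmax of the oracle ZNCC over the full fractional offset grid.

    Scans every offset of the centered M x M integer grid subdivided at
    pitch ``step``; ties break toward the smallest Euclidean offset, then
    scan order.
    """
    lo, hi = -(M // 2), M - M // 2 - 1
    k = round(1 / step)
    best = None
    for jy in range(lo * k, hi * k + 1):
        for jx in range(lo * k, hi * k + 1):
            dx, dy = jx * step, jy * step
            r = zncc_oracle(dr, drr, (dx, dy), ic, N, sigma, valid, min_valid)
            if math.isnan(r):
                continue
            key = (-r, dx * dx + dy * dy)
            if best is None or key < best[0]:
                best = (key, dx, dy, r)
    assert best is not None
    return best[1], best[2], best[3]


def couch_error_oracle(m, ref, meas, spacing):
    """Literal per-axis error transcription.

    m = (lat, vert, long) mm; ref/meas = (fdx, fdy, ldx, ldy) px.
    """
    fdx_r, fdy_r, ldx_r, ldy_r = ref
    fdx, fdy, ldx, ldy = meas
    e_lat = m[0] - (fdx_r - fdx) * spacing
    e_vert = m[1] - (ldx_r - ldx) * spacing
    e_long = m[2] - ((fdy_r - fdy) + (ldy_r - ldy)) / 2 * spacing
    return e_lat, e_vert, e_long


def pearson_oracle(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)
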