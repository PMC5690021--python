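"""Image and report I/O.

Reads 8- or 16-bit PNG/TIFF, gray or RGB; 8-bit intensities are rescaled
by 257 onto the 16-bit scale so the masking threshold keeps one meaning.
Masks are written as 0/255 single-channel PNG, cleaned images as 16-bit
PNG.  Run reports serialize to JSON and round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

from .config import MatchConfig
from .types import CapturedImage, ImageIOError, View

__all__ = [
    "read_captured",
    "write_image16",
    "write_mask",
    "RunReport",
    "file_sha256",
]


def read_captured(
    path: str | Path,
    view: View,
    pixel_spacing_mm: float,
    isocenter_px: tuple[float, float],
) -> CapturedImage:
    """Read a PNG/TIFF into a CapturedImage on the 16-bit intensity scale."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ImageIOError(f"{path}: unsupported image layout {arr.shape}")
    pixels = arr.astype(np.float64)
    if arr.dtype == np.uint8:
        pixels *= 257.0  # 8-bit -> 16-bit scale
    return CapturedImage(
        pixels=pixels,
        view=view,
        pixel_spacing_mm=pixel_spacing_mm,
        isocenter_px=isocenter_px,
    )


def write_image16(path: str | Path, pixels: np.ndarray) -> None:
    """Write an intensity grid as 16-bit PNG (gray) or TIFF (gray or RGB).

    16-bit RGB is not representable in the PNG encoder available here, so
    color frames must use a ``.tif``/``.tiff`` extension.
    """
    path = Path(path)
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 65535).round().astype(np.uint16)
    if arr.ndim == 3 and path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError("16-bit color frames must be written as TIFF (.tif)")
    iio.imwrite(path, arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Serializable record of one frontal+lateral registration run.

    Carries the per-view displacements, the couch-space error, the full
    config echo (sufficient to re-run bit-identically), input checksums
    and any warnings raised along the way.
    """

    frontal: dict[str, Any]
    lateral: dict[str, Any]
    error_mm: dict[str, float]
    config: dict[str, Any]
    inputs: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    @classmethod
    def read(cls, path: str | Path) -> "RunReport":
        return cls.from_json(Path(path).read_text())
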