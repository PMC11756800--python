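"""Raster conversion and preprocessing of pattern images.

Simulator fields are arbitrary real scalars; everything downstream works
on square grayscale images with intensities in [0, 1].  Preprocessing
before embedding comprises a Gaussian blur (to suppress the sharp/smooth
boundary cue that separates binary growth models from PDE models) and,
for external target images, a center-crop scan that compensates for the
unknown spatial scale of a photograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

DEFAULT_SIZE = 128
DEFAULT_BLUR_SIGMA = 1.5
CROP_RATIOS = tuple(round(0.50 + 0.05 * k, 2) for k in range(11))

__all__ = [
    "PatternImage",
    "normalize_field",
    "blur",
    "center_crop_series",
    "resize",
    "read_image",
    "write_image",
    "CROP_RATIOS",
    "DEFAULT_BLUR_SIGMA",
]


@dataclass
class PatternImage:
    """Square grayscale raster with intensities in [0, 1]."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("PatternImage must be square and 2-d")
        if not np.isfinite(self.pixels).all():
            raise ValueError("PatternImage contains non-finite values")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("PatternImage intensities must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def normalize_field(field: np.ndarray, provenance: str = "") -> PatternImage:
    """Min-max scale a raw field to [0, 1]; a constant field maps to 0.5."""
    arr = np.asarray(field, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("cannot normalize a field with non-finite values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-300:
        return PatternImage(np.full_like(arr, 0.5), provenance)
    return PatternImage((arr - lo) / (hi - lo), provenance)


def blur(image: PatternImage, sigma: float = DEFAULT_BLUR_SIGMA) -> PatternImage:
    """Gaussian low-pass with reflective padding; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("blur sigma must be >= 0")
    if sigma == 0:
        return PatternImage(image.pixels.copy(), image.provenance)
    out = gaussian_filter(image.pixels, sigma=sigma, mode="reflect")
    return PatternImage(np.clip(out, 0.0, 1.0), image.provenance)


def resize(image: PatternImage, size: int) -> PatternImage:
    """Bilinear resize to ``size`` x ``size``."""
    if image.size == size:
        return PatternImage(image.pixels.copy(), image.provenance)
    pil = Image.fromarray(np.uint8(np.round(image.pixels * 255.0)), mode="L")
    pil = pil.resize((size, size), Image.BILINEAR)
    return PatternImage(np.asarray(pil, dtype=float) / 255.0, image.provenance)


def center_crop_series(image: PatternImage, out_size: int | None = None):
    """Center crops at ratios 0.50, 0.55, ..., 1.00, each resized back.

    Returns a list of ``(ratio, PatternImage)`` pairs (always 11 entries).
    Odd crop windows round down to even sizes so the window stays centered
    at (side/2, side/2).
    """
    side = image.size
    out_size = out_size or side
    series = []
    for ratio in CROP_RATIOS:
        w = int(side * ratio)
        w -= w % 2
        w = max(w, 2)
        off = (side - w) // 2
        crop = PatternImage(image.pixels[off:off + w, off:off + w], image.provenance)
        series.append((ratio, resize(crop, out_size)))
    return series


def write_image(image: PatternImage, path) -> None:
    """Write as 8-bit grayscale PNG."""
    Image.fromarray(np.uint8(np.round(image.pixels * 255.0)), mode="L").save(path)


def read_image(path, square: str = "crop") -> PatternImage:
    """Read a PNG (or any PIL-readable raster) as a grayscale PatternImage.

    RGB input is converted by luminance.  Non-square input is made square
    per ``square``: "crop" center-crops to the short side, "pad" pads with
    the mean intensity to the long side.
    """
    try:
        pil = Image.open(path)
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"unreadable image file: {path}") from exc
    if pil.mode != "L":
        pil = pil.convert("L")  # PIL luminance conversion for RGB input
    arr = np.asarray(pil, dtype=float) / 255.0
    h, w = arr.shape
    if h != w:
        if square == "crop":
            s = min(h, w)
            oy, ox = (h - s) // 2, (w - s) // 2
            arr = arr[oy:oy + s, ox:ox + s]
        elif square == "pad":
            s = max(h, w)
            out = np.full((s, s), arr.mean())
            oy, ox = (s - h) // 2, (s - w) // 2
            out[oy:oy + h, ox:ox + w] = arr
            arr = out
        else:
            raise ValueError(f"unknown square mode: {square!r}")
    return PatternImage(arr, provenance=str(path))
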