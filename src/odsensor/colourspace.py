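"""Image decoding and CIELAB colour arithmetic.

Images are decoded to floating-point sRGB in ``[0, 1]`` and converted to the
CIE 1976 L*a*b* colour space under a D65 reference white, the standard
assumption for consumer-camera sRGB material.  All downstream clustering and
regression operates on CIELAB values, so this module is the single place
where colour conversions happen.
"""

from __future__ import annotations

import logging
import os
from typing import NamedTuple

import numpy as np
from PIL import Image, ImageOps
from skimage import color as _skcolor

__all__ = [
    "LabTriple",
    "load_image",
    "rgb_to_lab",
    "lab_to_rgb",
    "mean_lab",
    "read_mask",
    "write_mask",
]

log = logging.getLogger(__name__)


class LabTriple(NamedTuple):
    """A single CIELAB colour: lightness ``L`` and opponent axes ``a``, ``b``."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    def distance(self, other: "LabTriple") -> float:
        """Euclidean distance to another Lab colour."""
        return float(np.linalg.norm(self.as_array() - np.asarray(other, dtype=float)))


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Decode a PNG/JPEG file to an ``H x W x 3`` float array in ``[0, 1]``.

    EXIF orientation is honoured (phone cameras tag rotations rather than
    rotating pixels).  Alpha channels are dropped with a warning; images
    without three colour channels (e.g. grayscale) raise ``ValueError``.
    8- and 16-bit inputs are both normalised to ``[0, 1]``.
    """
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode in ("RGBA", "LA", "PA"):
                log.warning("dropping alpha channel of %s (mode %s)", path, im.mode)
                im = im.convert("RGB")
            if im.mode == "P":
                im = im.convert("RGB")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot decode image file {path!r}: {exc}") from exc

    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path!r} is not a 3-channel colour image (shape {arr.shape})"
        )
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB (components in ``[0, 1]``) to CIELAB, D65 white point.

    Accepts either a single image ``H x W x 3`` or a flat ``N x 3`` pixel
    list; the shape is preserved.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing colour axis of size 3, got {rgb.shape}")
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError("sRGB components must lie in [0, 1]")
    return _skcolor.rgb2lab(np.clip(rgb, 0.0, 1.0))


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse conversion; out-of-gamut colours are clipped into ``[0, 1]``."""
    lab = np.asarray(lab, dtype=np.float64)
    return _skcolor.lab2rgb(lab)


def mean_lab(lab: np.ndarray, mask: np.ndarray | None = None) -> LabTriple:
    """Arithmetic per-channel mean over selected pixels.

    With no mask the whole image is averaged (the illumination reference);
    with a boolean mask only the selected pixels contribute (a region of
    interest).  An empty selection is an error.
    """
    lab = np.asarray(lab, dtype=np.float64)
    pixels = lab.reshape(-1, 3)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != lab.shape[:-1]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image {lab.shape[:-1]}"
            )
        pixels = pixels[mask.reshape(-1)]
    if pixels.shape[0] == 0:
        raise ValueError("mean over an empty pixel selection")
    m = pixels.mean(axis=0)
    return LabTriple(float(m[0]), float(m[1]), float(m[2]))


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Store a boolean mask as a single-channel PNG (0 excluded, 255 included)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to a boolean array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128
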