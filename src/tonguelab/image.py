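"""Tongue image container and PNG I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["TongueImage", "load_tongue_image", "save_image", "save_mask", "load_mask"]


@dataclass
class TongueImage:
    """An 8-bit RGB raster with a binary tongue-region mask.

    Pixels outside ``tongue_mask`` are ignored by every feature operation.
    """

    pixels: np.ndarray  # HxWx3 uint8
    tongue_mask: np.ndarray  # HxW bool

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.tongue_mask = np.asarray(self.tongue_mask).astype(bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.tongue_mask.shape != self.pixels.shape[:2]:
            raise ValueError("tongue_mask shape must match pixels")
        if not self.tongue_mask.any():
            raise ValueError("tongue_mask must be nonempty")

    @property
    def shape(self):
        return self.pixels.shape[:2]


def load_tongue_image(image_path, mask_path=None) -> TongueImage:
    """Read an RGB raster (PNG/BMP/JPEG) and an optional 0/255 mask PNG.

    Without a mask the whole frame is treated as tongue.
    """
    pixels = np.asarray(Image.open(image_path).convert("RGB"))
    if mask_path is None:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    else:
        mask = load_mask(mask_path)
    return TongueImage(pixels, mask)


def save_image(pixels, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def save_mask(mask, path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128
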