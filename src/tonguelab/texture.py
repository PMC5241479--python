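"""Gray-level difference texture statistics (CON, ASM, ENT, MEAN).

Texture of the tongue body and coating (tender vs. rough body, greasy vs.
rough coating) shows up as local gray-level variation.  The descriptor used
here is the normalized histogram of absolute gray-level differences between
pixel pairs at a fixed displacement, summarized by four statistics:

* ``CON``  contrast, sum_i i^2 p(i)
* ``ASM``  angular second moment, sum_i p(i)^2
* ``ENT``  entropy, -sum_{p(i)>0} p(i) log2 p(i)  (bits; base configurable)
* ``MEAN`` first moment, sum_i i p(i)

Gray level is the rounded ITU-R BT.601 luminance (0.299 R + 0.587 G +
0.114 B).  By default statistics are computed at displacements (1, 0) and
(0, 1) and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "gray_difference_histogram",
    "texture_stats",
    "region_texture_features",
    "DifferenceHistogram",
    "TextureFeatures",
    "TEXTURE_FEATURE_NAMES",
    "luminance",
]

N_LEVELS = 256
TEXTURE_FEATURE_NAMES = ("CON", "ASM", "ENT", "MEAN")
DEFAULT_DISPLACEMENTS = ((1, 0), (0, 1))


def luminance(pixels) -> np.ndarray:
    """Rounded BT.601 luma of an HxWx3 8-bit image, as uint16 levels 0..255."""
    pixels = np.asarray(pixels, dtype=float)
    y = 0.299 * pixels[..., 0] + 0.587 * pixels[..., 1] + 0.114 * pixels[..., 2]
    return np.rint(y).astype(np.int64)


@dataclass
class DifferenceHistogram:
    """Normalized histogram of absolute gray differences at one displacement."""

    p: np.ndarray  # length-256 probability vector
    displacement: tuple

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_LEVELS,):
            raise ValueError(f"p must have length {N_LEVELS}")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be a probability vector")


@dataclass
class TextureFeatures:
    CON: float
    ASM: float
    ENT: float
    MEAN: float

    def as_dict(self, prefix: str = "") -> dict:
        return {f"{prefix}{k}": getattr(self, k) for k in TEXTURE_FEATURE_NAMES}

    @classmethod
    def empty(cls) -> "TextureFeatures":
        return cls(*([float("nan")] * 4))


def gray_difference_histogram(image, mask, displacement) -> DifferenceHistogram:
    """Histogram of |g(x) - g(x + d)| over pairs with both endpoints in mask.

    ``displacement`` is (dx, dy) = (column offset, row offset).  Raises
    ``ValueError`` if no pixel pair at that displacement lies fully inside
    the mask.
    """
    pixels = getattr(image, "pixels", image)
    gray = luminance(pixels)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape does not match image")
    dx, dy = int(displacement[0]), int(displacement[1])
    h, w = gray.shape
    # overlap of the mask with itself shifted by (dy rows, dx cols)
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"no valid pixel pairs for displacement {(dx, dy)}")
    m_here = mask[r0:r1, c0:c1]
    m_there = mask[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    valid = m_here & m_there
    if not valid.any():
        raise ValueError(f"no valid pixel pairs for displacement {(dx, dy)}")
    diffs = np.abs(
        gray[r0:r1, c0:c1][valid] - gray[r0 + dy : r1 + dy, c0 + dx : c1 + dx][valid]
    )
    counts = np.bincount(diffs, minlength=N_LEVELS).astype(float)
    return DifferenceHistogram(counts / counts.sum(), (dx, dy))


def texture_stats(hist: DifferenceHistogram, ent_base: float = 2.0) -> TextureFeatures:
    """CON, ASM, ENT, MEAN of a difference histogram."""
    p = hist.p
    i = np.arange(N_LEVELS, dtype=float)
    con = float(np.sum(i**2 * p))
    asm = float(np.sum(p**2))
    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log(nz) / np.log(ent_base)))
    mean = float(np.sum(i * p))
    return TextureFeatures(con, asm, ent, mean)


def region_texture_features(
    image, mask, displacements=DEFAULT_DISPLACEMENTS, ent_base: float = 2.0
) -> TextureFeatures:
    """Texture statistics of one region, averaged over displacements.

    An empty mask (absent coating) yields NaN features, flagged for later
    imputation.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return TextureFeatures.empty()
    stats = [
        texture_stats(gray_difference_histogram(image, mask, d), ent_base=ent_base)
        for d in displacements
    ]
    return TextureFeatures(
        *(float(np.mean([getattr(s, k) for s in stats])) for k in TEXTURE_FEATURE_NAMES)
    )
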