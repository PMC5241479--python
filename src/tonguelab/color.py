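"""Color-space conversions and per-region mean color features.

The tongue body is predominantly red while the coating is whitish/yellow, so
besides device RGB the pipeline records hue-saturation-intensity (HSI, arccos
hue formulation) and CIELAB coordinates for each segmented region.  Region
features are computed *mean-then-transform*: pixel RGB values are averaged
over the region mask first and the single mean color is then converted, which
matches reporting one color parameter set per region.

Conventions
-----------
* HSI: H in degrees in [0, 360); S and I in [0, 1].  Achromatic input
  (R = G = B, including black) gets H = 0 and S = 0 by convention.
* CIELAB: sRGB primaries and gamma, D65 reference white, CIE 1976 L*a*b*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "rgb_to_hsi",
    "hsi_to_rgb",
    "rgb_to_lab",
    "region_color_means",
    "ColorFeatures",
    "COLOR_FEATURE_NAMES",
]

# D65 white (2-degree observer) and the classic published 6-decimal
# sRGB -> XYZ matrix (original sRGB specification, BT.709 primaries).
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])
_RGB2XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

COLOR_FEATURE_NAMES = ("R", "G", "B", "H", "S", "I", "L", "a", "b")


def rgb_to_hsi(rgb):
    """Convert RGB in [0, 1] to (H, S, I).

    H is the arccos-formulation hue in degrees, reflected to (180, 360) when
    B > G; S = 1 - 3*min(R,G,B)/(R+G+B); I = (R+G+B)/3.  Black and achromatic
    inputs return H = 0, S = 0.

    Accepts a single triple or an (..., 3) array.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("rgb must have 3 components in the last axis")
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("rgb components must lie in [0, 1]")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    i = total / 3.0

    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1.0, 1.0)
        h = np.degrees(np.arccos(cosang))
    h = np.where(b > g, 360.0 - h, h)
    # achromatic pixels: zero chroma denominator => hue undefined, use 0
    h = np.where(den > 1e-12, h, 0.0)
    h = np.where(h >= 360.0, 0.0, h)
    if arr.ndim == 1:
        return float(h), float(s), float(i)
    return h, s, i


def hsi_to_rgb(h, s, i):
    """Inverse of :func:`rgb_to_hsi` for scalar inputs (sector formulation)."""
    h = float(h) % 360.0
    s, i = float(s), float(i)
    if s == 0:
        return (i, i, i)
    if h < 120.0:
        hr = np.radians(h)
        b = i * (1 - s)
        r = i * (1 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
        g = 3 * i - (r + b)
        return (r, g, b)
    if h < 240.0:
        hr = np.radians(h - 120.0)
        r = i * (1 - s)
        g = i * (1 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
        b = 3 * i - (r + g)
        return (r, g, b)
    hr = np.radians(h - 240.0)
    g = i * (1 - s)
    b = i * (1 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
    r = 3 * i - (g + b)
    return (r, g, b)


def _srgb_to_linear(c):
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t):
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab(rgb):
    """Convert an 8-bit RGB triple (or (..., 3) array) to CIE L*a*b* (D65).

    sRGB gamma expansion -> linear RGB -> XYZ -> L*a*b* with the standard
    piecewise cube-root function.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("rgb must have 3 components in the last axis")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("8-bit rgb components must lie in [0, 255]")
    linear = _srgb_to_linear(arr / 255.0)
    xyz = linear @ _RGB2XYZ.T
    fxyz = _lab_f(xyz / _WHITE_D65)
    L = 116.0 * fxyz[..., 1] - 16.0
    a = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    b = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    if arr.ndim == 1:
        return float(L), float(a), float(b)
    return L, a, b


@dataclass
class ColorFeatures:
    """Mean color of one region in RGB (8-bit), HSI, and CIELAB."""

    R: float
    G: float
    B: float
    H: float
    S: float
    I: float
    L: float
    a: float
    b: float
    missing: bool = field(default=False)

    def as_dict(self, prefix: str = "") -> dict:
        vals = {name: getattr(self, name) for name in COLOR_FEATURE_NAMES}
        return {f"{prefix}{k}": v for k, v in vals.items()}

    @classmethod
    def empty(cls) -> "ColorFeatures":
        """Placeholder for an absent region (e.g. no coating); all NaN."""
        return cls(*([float("nan")] * 9), missing=True)


def region_color_means(image, mask) -> ColorFeatures:
    """Mean RGB over ``mask`` pixels of ``image``, plus HSI and LAB transforms.

    ``image`` may be a TongueImage or an HxWx3 uint8 array.  An empty mask
    yields :meth:`ColorFeatures.empty` (the coating may be absent).
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        return ColorFeatures.empty()
    mean_rgb = pixels[mask].astype(float).mean(axis=0)
    h, s, i = rgb_to_hsi(mean_rgb / 255.0)
    L, a, b = rgb_to_lab(mean_rgb)
    return ColorFeatures(*mean_rgb, h, s, i, L, a, b)
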