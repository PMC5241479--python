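"""Tongue body vs. coating segmentation.

The body (reddish flesh) and the coating (whitish/yellow fur) differ chiefly
in color, so segmentation works on a chrominance map — by default the CIELAB
a* (red-green opponent) coordinate, where the red body scores high and the
pale coating low.  Two passes are combined:

1. **Division-merging**: the tongue is quadtree-split into blocks until each
   block's chrominance std is at most ``homogeneity_tol`` or the block has
   reached ``min_block_size``; blocks still inhomogeneous at the minimum size
   are split into single pixels.  Adjacent regions are then merged greedily
   in raster order while the merged std and the gap between the two region
   means both stay within tolerance.
2. **Chrominance threshold**: region means are split by Otsu's criterion
   (pixel-weighted), regions labeled body/coating by which side of the
   threshold they fall on.  Regions whose mean lies within
   ``homogeneity_tol`` of the threshold — the thin-coating situation where
   body and coating colors overlap — are re-labeled pixel by pixel against
   the same threshold, as are regions that stayed inhomogeneous.

A unimodal chrominance histogram (no coating to find) yields the whole
tongue labeled body, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .color import rgb_to_lab

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "Region",
    "chrominance_map",
    "division_merge",
    "segment_body_coating",
    "CHROMA_CHANNELS",
]

CHROMA_CHANNELS = ("a", "hue", "rg")


@dataclass
class SegmentationConfig:
    min_block_size: int = 4  # block side length, px
    homogeneity_tol: float = 6.0  # max within-region chrominance std
    chroma_channel: str = "a"
    threshold_mode: str = "automatic"  # automatic (Otsu) | fixed
    fixed_threshold: float | None = None

    def validate(self):
        if self.min_block_size < 2:
            raise ValueError("min_block_size must be >= 2")
        if self.homogeneity_tol <= 0:
            raise ValueError("homogeneity_tol must be > 0")
        if self.chroma_channel not in CHROMA_CHANNELS:
            raise ValueError(f"unknown chrominance channel {self.chroma_channel!r}")
        if self.threshold_mode not in ("automatic", "fixed"):
            raise ValueError("threshold_mode must be 'automatic' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_mode requires fixed_threshold")


@dataclass
class Region:
    """One homogeneous region produced by division-merging."""

    mask: np.ndarray
    mean: float
    std: float
    count: int


@dataclass
class SegmentationResult:
    body_mask: np.ndarray
    coating_mask: np.ndarray
    method_trace: dict = field(default_factory=dict)


def chrominance_map(image, channel: str = "a") -> np.ndarray:
    """Per-pixel chrominance of the tongue region; NaN outside the mask.

    Channels: ``"a"`` CIELAB a* (red-green opponent, the default — red body
    high, pale coating low), ``"hue"`` HSI hue in degrees, ``"rg"`` the raw
    R - G difference.
    """
    if channel not in CHROMA_CHANNELS:
        raise ValueError(f"unknown chrominance channel {channel!r}")
    pixels = np.asarray(image.pixels, dtype=float)
    if channel == "a":
        _, cmap, _ = rgb_to_lab(pixels)
    elif channel == "rg":
        cmap = pixels[..., 0] - pixels[..., 1]
    else:  # hue
        from .color import rgb_to_hsi

        cmap, _, _ = rgb_to_hsi(pixels / 255.0)
    out = np.where(image.tongue_mask, cmap, np.nan)
    return out


def _quadtree_leaves(values, mask, tol, min_side):
    """Yield (r0, r1, c0, c1) leaf blocks covering the mask's bounding box."""
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    stack = [(rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)]
    leaves = []
    while stack:
        r0, r1, c0, c1 = stack.pop()
        sub = mask[r0:r1, c0:c1]
        if not sub.any():
            continue
        vals = values[r0:r1, c0:c1][sub]
        # homogeneous = low std AND no extreme outlier (a single contaminant
        # pixel in a large block barely moves the std but doubles the range)
        if (vals.std() <= tol and np.ptp(vals) <= 2 * tol) or max(r1 - r0, c1 - c0) <= min_side:
            leaves.append((r0, r1, c0, c1))
            continue
        rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
        rm = max(rm, r0 + 1) if r1 - r0 > 1 else r1
        cm = max(cm, c0 + 1) if c1 - c0 > 1 else c1
        # split into up to 4 quadrants
        row_cuts = [(r0, rm), (rm, r1)] if rm < r1 else [(r0, r1)]
        col_cuts = [(c0, cm), (cm, c1)] if cm < c1 else [(c0, c1)]
        for rr in row_cuts:
            for cc in col_cuts:
                stack.append((rr[0], rr[1], cc[0], cc[1]))
    return leaves


def division_merge(image, cfg: SegmentationConfig | None = None, values=None):
    """Split-and-merge the tongue into chrominance-homogeneous regions.

    Returns a list of :class:`Region` whose masks tile the tongue mask.
    Merging is greedy pairwise in raster order of region creation; a merge
    is accepted while the merged chrominance std and the difference of the
    two region means both stay within ``homogeneity_tol``, ties broken by
    lower region index.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    mask = np.asarray(image.tongue_mask, dtype=bool)
    if not mask.any():
        raise ValueError("tongue mask is empty")
    if values is None:
        values = chrominance_map(image, cfg.chroma_channel)
    tol = cfg.homogeneity_tol

    labels = np.full(mask.shape, -1, dtype=np.int64)
    next_id = 0
    for r0, r1, c0, c1 in sorted(_quadtree_leaves(values, mask, tol, cfg.min_block_size)):
        sub = mask[r0:r1, c0:c1]
        vals = values[r0:r1, c0:c1][sub]
        if vals.std() > tol or np.ptp(vals) > 2 * tol:
            # residual inhomogeneous minimal block: each pixel its own region
            rr, cc = np.nonzero(sub)
            for dr, dc in zip(rr, cc):
                labels[r0 + dr, c0 + dc] = next_id
                next_id += 1
        else:
            labels[r0:r1, c0:c1][sub] = next_id
            next_id += 1

    # region statistics
    flat = labels[mask]
    vals = values[mask]
    n = np.bincount(flat, minlength=next_id).astype(float)
    s1 = np.bincount(flat, weights=vals, minlength=next_id)
    s2 = np.bincount(flat, weights=vals**2, minlength=next_id)

    # adjacency from 4-neighborhood
    adj = {i: set() for i in range(next_id) if n[i] > 0}
    for a, b in (
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
    ):
        pairs = np.stack([a.ravel(), b.ravel()], axis=1)
        pairs = pairs[(pairs[:, 0] >= 0) & (pairs[:, 1] >= 0) & (pairs[:, 0] != pairs[:, 1])]
        for i, j in np.unique(pairs, axis=0):
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))

    alias = np.arange(next_id)

    def mergeable(i, j):
        # merged std alone is insensitive to absorbing a tiny region into a
        # huge one, so also require the region means to agree within tol
        if abs(s1[i] / n[i] - s1[j] / n[j]) > tol:
            return False
        nn = n[i] + n[j]
        m = (s1[i] + s1[j]) / nn
        return np.sqrt(max((s2[i] + s2[j]) / nn - m * m, 0.0)) <= tol

    changed = True
    while changed:
        changed = False
        for i in sorted(adj):
            if i not in adj:
                continue
            for j in sorted(adj[i]):
                if j not in adj or j == i:
                    continue
                if mergeable(i, j):
                    n[i] += n[j]
                    s1[i] += s1[j]
                    s2[i] += s2[j]
                    for k in adj.pop(j):
                        if k == i:
                            continue
                        adj[k].discard(j)
                        adj[k].add(i)
                        adj[i].add(k)
                    adj[i].discard(j)
                    alias[alias == alias[j]] = i
                    alias[j] = i
                    changed = True

    labels = np.where(mask, alias[np.clip(labels, 0, None)], -1)
    regions = []
    for rid in sorted(adj):
        rmask = labels == rid
        cnt = int(n[rid])
        mean = s1[rid] / n[rid]
        std = np.sqrt(max(s2[rid] / n[rid] - mean * mean, 0.0))
        regions.append(Region(rmask, float(mean), float(std), cnt))
    return regions


def otsu_threshold(values) -> float:
    """Exact Otsu threshold of a sample.

    Between-class variance is maximized over the midpoints of consecutive
    distinct values (no histogram binning), so the returned threshold falls
    mid-gap between the two modes rather than at a bin edge.
    """
    v = np.sort(np.asarray(values, dtype=float))
    distinct = np.unique(v)
    if len(distinct) < 2:
        raise ValueError("need at least two distinct values")
    candidates = 0.5 * (distinct[:-1] + distinct[1:])
    n = len(v)
    csum = np.cumsum(v)
    best_t, best_var = candidates[0], -np.inf
    for t in candidates:
        k = np.searchsorted(v, t)
        w0 = k / n
        mu0 = csum[k - 1] / k
        mu1 = (csum[-1] - csum[k - 1]) / (n - k)
        var = w0 * (1 - w0) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def segment_body_coating(image, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Label every tongue pixel body or coating.

    Division-merge regions are labeled by thresholding their mean
    chrominance; border-zone regions (mean within ``homogeneity_tol`` of the
    threshold) and residually inhomogeneous regions are re-labeled per pixel.
    Body is the side of the threshold with the higher mean CIELAB a*.
    """
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    values = chrominance_map(image, cfg.chroma_channel)
    regions = division_merge(image, cfg, values=values)
    tongue = np.asarray(image.tongue_mask, dtype=bool)
    trace = {
        "n_regions": len(regions),
        "channel": cfg.chroma_channel,
    }

    means = np.array([r.mean for r in regions])
    pixel_region_mean = np.zeros(tongue.shape)
    for r in regions:
        pixel_region_mean[r.mask] = r.mean

    degenerate = False
    if cfg.threshold_mode == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if np.ptp(means) < 1e-12:
            degenerate = True
            thr = float(means[0])
        else:
            thr = otsu_threshold(pixel_region_mean[tongue])
            lo = pixel_region_mean[tongue] <= thr
            # unimodal histogram: the Otsu split does not separate the modes
            # by more than the homogeneity tolerance, or one "mode" is just a
            # handful of outlier pixels (< 1% of the tongue)
            if (
                not lo.any()
                or lo.all()
                or pixel_region_mean[tongue][~lo].mean() - pixel_region_mean[tongue][lo].mean()
                <= cfg.homogeneity_tol
                or min(lo.mean(), 1.0 - lo.mean()) < 0.01
            ):
                degenerate = True
    trace["threshold"] = thr

    if degenerate:
        warnings.warn(
            "chrominance histogram is unimodal; labeling entire tongue as body",
            stacklevel=2,
        )
        trace["degenerate"] = True
        return SegmentationResult(tongue.copy(), np.zeros_like(tongue), trace)

    high = np.zeros_like(tongue)
    n_pixelwise = 0
    for r in regions:
        borderline = abs(r.mean - thr) <= cfg.homogeneity_tol or r.std > cfg.homogeneity_tol
        if borderline:
            high |= r.mask & (values > thr)
            n_pixelwise += 1
        elif r.mean > thr:
            high |= r.mask
    low = tongue & ~high
    trace["n_regions_pixelwise"] = n_pixelwise

    # cleanup: flip pixels whose own chrominance lies beyond tol on the
    # wrong side of the threshold (stray pixels absorbed by block merging)
    flip_to_low = high & (values < thr - cfg.homogeneity_tol)
    flip_to_high = low & (values > thr + cfg.homogeneity_tol)
    high = (high & ~flip_to_low) | flip_to_high
    low = tongue & ~high

    # body = the side with higher red-green opponent a*
    if cfg.chroma_channel == "a":
        avals = values
    else:
        avals = chrominance_map(image, "a")
    a_high = avals[high].mean() if high.any() else -np.inf
    a_low = avals[low].mean() if low.any() else -np.inf
    if a_high >= a_low:
        body, coating = high, low
    else:
        body, coating = low, high
    if not body.any():
        # threshold put every pixel in the coating class: treat as degenerate
        warnings.warn("no body pixels found; labeling entire tongue as body", stacklevel=2)
        trace["degenerate"] = True
        return SegmentationResult(tongue.copy(), np.zeros_like(tongue), trace)
    return SegmentationResult(body, coating, trace)
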