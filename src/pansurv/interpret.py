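"""Attention heatmaps: percentile normalization of patch attention scores,
spatial mapping onto slide geometry, and RGB overlay rendering."""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from scipy import ndimage

from .core import ValidationError
from .preprocess import GeometryError


def percentile_normalize(scores, mode: str = "rank") -> np.ndarray:
    """Scale scores to [0, 1].

    ``rank`` (default): empirical percentile-rank transform, rank/(N-1) with
    midranks for ties — minimum maps to 0, maximum to 1, a single score to
    0.5.  ``winsor``: min-max scaling after clipping at the 1st/99th
    percentiles.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 1:
        raise ValidationError("scores must be a nonempty 1-D array")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite attention scores")
    n = len(scores)
    if n == 1:
        return np.array([0.5])
    if mode == "rank":
        order = np.argsort(scores, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n, dtype=float)
        # midranks for ties
        for v in np.unique(scores):
            tied = scores == v
            if tied.sum() > 1:
                ranks[tied] = ranks[tied].mean()
        return ranks / (n - 1)
    elif mode == "winsor":
        lo, hi = np.percentile(scores, [1, 99])
        clipped = np.clip(scores, lo, hi)
        if hi == lo:
            return np.full(n, 0.5)
        return (clipped - lo) / (hi - lo)
    raise ValidationError(f"unknown mode {mode!r}")


def render_heatmap(
    coords,
    scores,
    slide_dims: tuple[int, int],
    patch_size: int = 224,
    downsample: float = 32.0,
    smooth: bool = True,
) -> np.ndarray:
    """Paint each tile footprint with its normalized score at a working
    downsample; optionally smooth (Gaussian, approximating the bilinear
    interpolation used when upscaling to full resolution).  Unscored regions
    stay 0; output values stay in [0, 1]."""
    coords = np.asarray(coords).reshape(-1, 2)
    scores = np.asarray(scores, dtype=float)
    W, H = slide_dims
    if np.any(scores < -1e-9) or np.any(scores > 1 + 1e-9):
        raise ValidationError("scores must be normalized to [0, 1]")
    if np.any(coords < 0) or np.any(coords[:, 0] + patch_size > W) or np.any(
        coords[:, 1] + patch_size > H
    ):
        raise GeometryError("tile coordinates outside slide bounds")
    w = max(1, int(np.ceil(W / downsample)))
    h = max(1, int(np.ceil(H / downsample)))
    raster = np.zeros((h, w))
    for (x, y), s in zip(coords, scores):
        x0, y0 = int(np.floor(x / downsample)), int(np.floor(y / downsample))
        x1 = int(np.ceil((x + patch_size) / downsample))
        y1 = int(np.ceil((y + patch_size) / downsample))
        raster[y0:min(y1, h), x0:min(x1, w)] = s
    if smooth:
        sigma = max(patch_size / downsample / 4.0, 0.5)
        raster = ndimage.gaussian_filter(raster, sigma=sigma)
    return np.clip(raster, 0.0, 1.0)


def overlay(
    thumbnail: np.ndarray,
    heatmap: np.ndarray,
    alpha: float = 0.3,
    cmap: str = "viridis",
) -> np.ndarray:
    """Blend a colormapped heatmap over an RGB thumbnail:
    out = (1 - alpha) * thumbnail + alpha * colormap(heatmap)."""
    thumbnail = np.asarray(thumbnail, dtype=float)
    heatmap = np.asarray(heatmap, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if thumbnail.ndim != 3 or thumbnail.shape[2] != 3:
        raise GeometryError("thumbnail must be H x W x 3")
    if thumbnail.shape[:2] != heatmap.shape:
        raise GeometryError(
            f"thumbnail {thumbnail.shape[:2]} and heatmap {heatmap.shape} disagree"
        )
    colored = colormaps[cmap](heatmap)[..., :3] * 255.0
    out = (1.0 - alpha) * thumbnail + alpha * colored
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
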