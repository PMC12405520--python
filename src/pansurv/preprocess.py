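"""Slide raster -> feature bag: Otsu tissue masking, grid tiling, encoding.

Works on plain RGB rasters (numpy arrays, PNG/TIFF via Pillow).  Pyramidal
scanner formats can be supported by implementing the small ``SlideReader``
protocol; the magnification convention is microns-per-pixel (target 1.0 mpp,
i.e. the usual "10x"), which is portable across scanners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from PIL import Image

from .core import DimensionError, FeatureBag, ValidationError


class GeometryError(ValueError):
    """Raised when mask/slide/tile geometries disagree."""


# ---------------------------------------------------------------- tissue mask
@dataclass
class TissueMask:
    mask: np.ndarray              # binary, thumbnail resolution
    downsample_factor: float
    threshold: int
    degenerate: bool = False      # constant-intensity input: no valid threshold

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.downsample_factor < 1:
            raise ValidationError("downsample_factor must be >= 1")


def otsu_threshold(hist: np.ndarray) -> int | None:
    """Otsu's threshold for a 256-bin histogram.

    Returns the t in [0, 255] maximizing between-class variance, where the low
    class is {0..t} and the high class {t+1..255}; ties resolve to the smallest
    t.  Returns None when one class would always be empty (constant image).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValidationError("histogram must have 256 bins")
    total = hist.sum()
    if total == 0 or np.count_nonzero(hist) < 2:
        return None
    p = hist / total
    omega = np.cumsum(p)                      # P(class0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # partial means
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def _saturation_channel(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.float64) / 255.0
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return np.round(sat * 255.0).astype(np.uint8)


def compute_otsu_mask(
    thumbnail: np.ndarray,
    channel: str = "saturation",
    downsample_factor: float = 32.0,
) -> TissueMask:
    """Threshold a thumbnail into tissue/background with Otsu's method.

    On the saturation channel tissue is the high-saturation side (H&E tissue
    is chromatic, glass background is achromatic); on grayscale tissue is the
    low-luminance side.  A constant-intensity thumbnail has no valid threshold
    and yields an all-background mask flagged ``degenerate``.
    """
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValidationError("empty thumbnail")
    if channel == "saturation":
        if thumbnail.ndim != 3:
            raise ValidationError("saturation channel requires an RGB thumbnail")
        img = _saturation_channel(thumbnail)
        tissue_high = True
    elif channel == "grayscale":
        img = (
            thumbnail
            if thumbnail.ndim == 2
            else np.round(thumbnail.astype(np.float64).mean(axis=-1))
        ).astype(np.uint8)
        tissue_high = False
    else:
        raise ValidationError(f"unknown channel {channel!r}")

    hist = np.bincount(img.ravel(), minlength=256)[:256]
    t = otsu_threshold(hist)
    if t is None:
        warnings.warn("constant-intensity thumbnail: returning all-background mask")
        return TissueMask(
            mask=np.zeros(img.shape, dtype=np.uint8),
            downsample_factor=downsample_factor,
            threshold=0,
            degenerate=True,
        )
    mask = (img > t) if tissue_high else (img <= t)
    return TissueMask(
        mask=mask.astype(np.uint8),
        downsample_factor=downsample_factor,
        threshold=t,
    )


# -------------------------------------------------------------------- tiling
@dataclass
class TileGrid:
    coords: np.ndarray            # (n, 2) int, level-0 (x, y) tile origins
    patch_size_px: int
    tissue_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.tissue_fraction = np.asarray(self.tissue_fraction, dtype=float)

    def __len__(self):
        return len(self.coords)


def tile_slide(
    slide_dims: tuple[int, int],
    mask: TissueMask | None = None,
    patch_size_px: int = 224,
    min_tissue_fraction: float = 0.25,
    target_mpp: float = 1.0,
    native_mpp: float = 1.0,
) -> TileGrid:
    """Lay a non-overlapping patch grid over the slide and filter by tissue.

    The grid has stride = patch size, origin (0, 0); partial edge tiles are
    dropped, so the unfiltered count is floor(W/p) * floor(H/p) with p the
    patch size expressed at level 0 (scaled by target_mpp / native_mpp).  A
    tile is kept iff its mask-projected tissue fraction >= min_tissue_fraction.
    """
    W, H = slide_dims
    if not 0 <= min_tissue_fraction <= 1:
        raise ValidationError("min_tissue_fraction must be in [0, 1]")
    scale = target_mpp / native_mpp
    p0 = int(round(patch_size_px * scale))   # tile edge in level-0 pixels
    nx, ny = W // p0, H // p0
    if nx == 0 or ny == 0:
        warnings.warn(f"slide {W}x{H} smaller than one {p0}px tile: empty grid")
        return TileGrid(coords=np.zeros((0, 2)), patch_size_px=patch_size_px)

    xs, ys = np.meshgrid(np.arange(nx) * p0, np.arange(ny) * p0)
    coords = np.stack([xs.ravel(), ys.ravel()], axis=1)

    if mask is None:
        frac = np.ones(len(coords))
    else:
        mh, mw = mask.mask.shape
        ds = mask.downsample_factor
        if mw * ds < W * 0.5 or mh * ds < H * 0.5:
            raise GeometryError(
                f"mask geometry {mw}x{mh} @ {ds}x inconsistent with slide {W}x{H}"
            )
        frac = np.empty(len(coords))
        for i, (x, y) in enumerate(coords):
            x0, x1 = int(np.floor(x / ds)), int(np.ceil((x + p0) / ds))
            y0, y1 = int(np.floor(y / ds)), int(np.ceil((y + p0) / ds))
            window = mask.mask[y0:min(y1, mh), x0:min(x1, mw)]
            frac[i] = window.mean() if window.size else 0.0
    keep = frac >= min_tissue_fraction
    return TileGrid(
        coords=coords[keep], patch_size_px=patch_size_px, tissue_fraction=frac[keep]
    )


# ------------------------------------------------------------------ encoding
class PatchEncoder(Protocol):
    """Pluggable patch encoder: batch of RGB patches -> batch of D-vectors."""

    name: str
    dim: int

    def encode(self, patches: np.ndarray) -> np.ndarray:  # pragma: no cover
        ...


class StubEncoder:
    """Deterministic test encoder: fixed random projection of mean patch color.

    Stands in for a pathology foundation-model encoder during testing; it is
    deterministic for fixed seed and input, which is all the pipeline contracts
    require of an encoder.
    """

    def __init__(self, dim: int = 16, seed: int = 0):
        self.name = f"stub-{dim}-{seed}"
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((3, dim))

    def encode(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        mean_rgb = patches.reshape(patches.shape[0], -1, 3).mean(axis=1) / 255.0
        return mean_rgb @ self._proj


class SlideReader(Protocol):
    """Minimal slide access: dimensions and region reads at level 0."""

    @property
    def dims(self) -> tuple[int, int]:  # pragma: no cover
        ...

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:  # pragma: no cover
        ...


class ArraySlide:
    """In-memory RGB raster satisfying the SlideReader protocol."""

    def __init__(self, rgb: np.ndarray, mpp: float = 1.0):
        self.rgb = np.asarray(rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("ArraySlide expects an H x W x 3 raster")
        self.mpp = mpp

    @classmethod
    def from_file(cls, path: str | Path, mpp: float = 1.0) -> "ArraySlide":
        return cls(np.asarray(Image.open(path).convert("RGB")), mpp=mpp)

    @property
    def dims(self) -> tuple[int, int]:
        h, w = self.rgb.shape[:2]
        return (w, h)

    def thumbnail(self, downsample: float = 32.0) -> np.ndarray:
        w, h = self.dims
        tw, th = max(1, int(w / downsample)), max(1, int(h / downsample))
        img = Image.fromarray(self.rgb).resize((tw, th), Image.BILINEAR)
        return np.asarray(img)

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        W, H = self.dims
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise GeometryError(f"region ({x},{y},{w},{h}) outside slide {W}x{H}")
        return self.rgb[y : y + h, x : x + w]


def encode_tiles(
    slide: SlideReader,
    grid: TileGrid,
    encoder: PatchEncoder,
    slide_id: str = "slide",
    magnification: str = "10x",
    batch_size: int = 64,
) -> FeatureBag:
    """Encode every retained tile into a feature bag (rows in grid order)."""
    n = len(grid)
    if n == 0:
        raise ValidationError("empty tile grid: nothing to encode")
    feats = np.empty((n, encoder.dim), dtype=np.float32)
    p = grid.patch_size_px
    for start in range(0, n, batch_size):
        block = grid.coords[start : start + batch_size]
        patches = np.stack([slide.read_region(int(x), int(y), p, p) for x, y in block])
        out = np.asarray(encoder.encode(patches))
        if out.shape != (len(block), encoder.dim):
            raise DimensionError(
                f"encoder {encoder.name!r} declared dim {encoder.dim} but returned "
                f"shape {out.shape}"
            )
        feats[start : start + len(block)] = out
    return FeatureBag(
        slide_id=slide_id,
        features=feats,
        coords=grid.coords.astype(np.int32),
        patch_size_px=p,
        magnification=magnification,
        encoder_name=encoder.name,
    )
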