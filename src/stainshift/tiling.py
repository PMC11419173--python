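"""ROI masking, random tile sampling, and training-time augmentation.

Geometry convention, used everywhere: 0-based (row, col) coordinates and
half-open windows.  A tile's source window is 512x512 at full (40x)
resolution; tiles are 2x2-mean-pooled to 256x256 (the 20x working scale)
and randomly cropped to 224x224 at training time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import rng_from

log = logging.getLogger(__name__)

SOURCE_TILE = 512
TILE_SIZE = 256
CROP_SIZE = 224

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class InsufficientTissueError(ValueError):
    """Raised when a slide's mask offers no valid tile center."""


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, same height/width as the slide
    provenance: str  # "otsu" or "annotation&otsu"
    threshold: int = 0


@dataclass
class Tile:
    pixels: np.ndarray  # (256, 256, 3) uint8
    origin: tuple[int, int]  # (row, col) of the 512x512 source window
    slide_id: str = ""
    patient_id: int = -1
    batch: str = ""
    label: int = -1


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold of a 256-bin histogram.

    The returned value ``t`` splits pixels into ``gray < t`` versus
    ``gray >= t``; ties are broken toward the smallest qualifying
    threshold.  A single-populated-bin histogram is degenerate: the bin
    value itself is returned with a warning.
    """
    hist = np.asarray(gray_histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        warnings.warn("degenerate single-valued histogram for Otsu threshold")
        return int(nonzero[0])

    levels = np.arange(256, dtype=float)
    total = hist.sum()
    cum_n = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)
    # candidate thresholds t = 1..255; class 0 = {g < t}
    w0 = cum_n[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(cum_s[:-1], w0, out=np.zeros(255), where=w0 > 0)
    mu1 = np.divide(cum_s[-1] - cum_s[:-1], w1, out=np.zeros(255), where=w1 > 0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(between)) + 1


def _luma_u8(slide: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(slide.astype(float) @ _LUMA), 0, 255).astype(np.uint8)


def tissue_mask(slide: np.ndarray, annotation: np.ndarray | None = None) -> TissueMask:
    """Foreground = stained (dark) pixels inside the optional annotation.

    The Otsu threshold is computed on the luma histogram restricted to
    the annotated region when one is given; the mask is the intersection
    of the darker-than-threshold class with the annotation.
    """
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError("slide must be an RGB image")
    gray = _luma_u8(slide)
    if annotation is not None:
        annotation = np.asarray(annotation)
        if annotation.shape != gray.shape:
            raise ValueError("annotation shape must match the slide")
        ann = annotation > 0
        region = gray[ann]
        if region.size == 0:
            return TissueMask(np.zeros_like(ann), "annotation&otsu", 0)
        hist = np.bincount(region, minlength=256)[:256]
    else:
        ann = None
        hist = np.bincount(gray.ravel(), minlength=256)[:256]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = otsu_threshold(hist)
    mask = gray < thr
    if ann is not None:
        mask &= ann
        return TissueMask(mask, "annotation&otsu", thr)
    return TissueMask(mask, "otsu", thr)


def _downsample2(window: np.ndarray) -> np.ndarray:
    h, w, c = window.shape
    pooled = window.reshape(h // 2, 2, w // 2, 2, c).mean(axis=(1, 3))
    return np.rint(pooled).astype(np.uint8)


def sample_tiles(
    slide: np.ndarray,
    mask: TissueMask,
    n_tiles: int,
    seed: int,
    min_foreground_frac: float = 0.0,
    slide_id: str = "",
    patient_id: int = -1,
    batch: str = "",
    label: int = -1,
) -> list[Tile]:
    """Uniformly sample ``n_tiles`` mask-centered 512-windows, pooled to 256.

    Valid tile centers are mask-foreground pixels whose 512x512 window
    lies fully inside the slide (optionally also requiring a minimum mask
    fraction inside the window).  Sampling is without replacement when
    enough centers exist, otherwise with replacement (logged).
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be positive")
    h, w = slide.shape[:2]
    if h < SOURCE_TILE or w < SOURCE_TILE:
        raise ValueError(f"slide must be at least {SOURCE_TILE}x{SOURCE_TILE}")
    if mask.mask.shape != (h, w):
        raise ValueError("mask shape must match the slide")

    half = SOURCE_TILE // 2
    # center (r+half, c+half) for origin r in [0, h-512]
    center_region = mask.mask[half : h - SOURCE_TILE + half + 1, half : w - SOURCE_TILE + half + 1]
    if min_foreground_frac > 0.0:
        m = mask.mask.astype(np.float64)
        sat = np.pad(m.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
        s = SOURCE_TILE
        win_sum = (
            sat[s:, s:]
            - sat[:-s, s:]
            - sat[s:, :-s]
            + sat[:-s, :-s]
        )
        center_region = center_region & (win_sum / (s * s) >= min_foreground_frac)
    valid = np.flatnonzero(center_region)
    if valid.size == 0:
        raise InsufficientTissueError(
            f"slide {slide_id or '<unnamed>'}: no valid tile centers"
        )
    rng = rng_from(seed, "tiles", slide_id)
    if valid.size >= n_tiles:
        chosen = rng.choice(valid, size=n_tiles, replace=False)
    else:
        log.warning(
            "slide %s: only %d valid centers for %d tiles; sampling with replacement",
            slide_id or "<unnamed>",
            valid.size,
            n_tiles,
        )
        chosen = rng.choice(valid, size=n_tiles, replace=True)

    width_region = center_region.shape[1]
    tiles = []
    for flat in chosen:
        r, c = divmod(int(flat), width_region)
        window = slide[r : r + SOURCE_TILE, c : c + SOURCE_TILE]
        tiles.append(
            Tile(
                pixels=_downsample2(window),
                origin=(r, c),
                slide_id=slide_id,
                patient_id=patient_id,
                batch=batch,
                label=label,
            )
        )
    return tiles


def augment_tile(tile: Tile | np.ndarray, rng_seed: int) -> np.ndarray:
    """Right-angle rotation, independent flips, then a random 224 crop."""
    pixels = tile.pixels if isinstance(tile, Tile) else tile
    if pixels.shape[:2] != (TILE_SIZE, TILE_SIZE):
        raise ValueError(f"tile must be {TILE_SIZE}x{TILE_SIZE}")
    rng = np.random.default_rng(rng_seed)
    out = np.rot90(pixels, k=int(rng.integers(4)))
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    max_off = TILE_SIZE - CROP_SIZE
    r = int(rng.integers(max_off + 1))
    c = int(rng.integers(max_off + 1))
    return np.ascontiguousarray(out[r : r + CROP_SIZE, c : c + CROP_SIZE])


def center_crop(tile: Tile | np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Deterministic central crop used at inference time."""
    pixels = tile.pixels if isinstance(tile, Tile) else tile
    h, w = pixels.shape[:2]
    r = (h - size) // 2
    c = (w - size) // 2
    return pixels[r : r + size, c : c + size]
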