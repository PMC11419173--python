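"""Optical-density color model and structure-preserving stain normalization.

The color of an H&E image is modelled through the Beer-Lambert law:
optical density OD = -ln(I / I0) is linear in stain concentration,
OD ~= W @ C with W a 3x2 non-negative stain matrix (unit columns,
hematoxylin first) and C >= 0 the per-pixel concentrations.  W is
estimated by sparse non-negative matrix factorization — an alternating
scheme of L1-penalized non-negative coding and a multiplicative
dictionary update, initialized from the extreme angles of the top-2
SVD plane of the OD cloud.  "Traditional" normalization refactors a
tile in its own basis and recomposes it with a target basis and robust
concentration scaling, leaving the spatial concentration pattern (the
morphology) untouched.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import tiling
from ._rng import child_seed

log = logging.getLogger(__name__)

I0_DEFAULT = 255.0


class InsufficientStainError(ValueError):
    """Too few stained pixels to estimate a stain matrix."""


class StainDegeneracyError(ValueError):
    """The two estimated stain directions are (nearly) collinear."""


def rgb_to_od(rgb: np.ndarray, I0: float | np.ndarray = I0_DEFAULT) -> np.ndarray:
    """OD = -ln(clip(I, 1, I0) / I0), elementwise (natural log)."""
    i0 = np.asarray(I0, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("I0 must be positive")
    intensity = np.clip(np.asarray(rgb, dtype=float), 1.0, i0)
    return -np.log(intensity / i0)


def od_to_rgb(od: np.ndarray, I0: float | np.ndarray = I0_DEFAULT) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_od` up to 8-bit rounding."""
    i0 = np.asarray(I0, dtype=float)
    img = np.rint(i0 * np.exp(-np.asarray(od, dtype=float)))
    return np.clip(img, 0, 255).astype(np.uint8)


def hematoxylin_first(w: np.ndarray) -> np.ndarray:
    """Order columns so hematoxylin (larger red-to-blue OD ratio) is first.

    Hematoxylin looks blue-purple because it absorbs red strongly, so its
    OD column has the larger red (index 0) relative to blue (index 2)
    component; eosin (pink) is the opposite.
    """
    eps = 1e-12
    ratios = w[0, :] / (w[2, :] + eps)
    order = np.argsort(-ratios)
    return w[:, order]


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosv = float(np.clip(abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))
    return float(np.degrees(np.arccos(cosv)))


def stain_angles_deg(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Per-column angular distance (degrees) between two stain matrices."""
    return np.array([_angle_deg(w1[:, j], w2[:, j]) for j in range(w1.shape[1])])


def _coordinate_descent(
    a: np.ndarray, w: np.ndarray, lam: float, n_iter: int, c0: np.ndarray | None = None
) -> np.ndarray:
    """min_{C>=0} ||A - W C||_F^2 + lam * sum(C), vectorized over pixels.

    A is (3, N); returns C (2, N).  For two stains, cyclic coordinate
    descent converges to the exact solution (lam = 0 gives plain NNLS).
    """
    g = w.T @ w  # (2, 2)
    b = w.T @ a  # (2, N)
    c = np.zeros_like(b) if c0 is None else c0.copy()
    for _ in range(n_iter):
        c[0] = np.maximum(0.0, (b[0] - g[0, 1] * c[1] - lam / 2.0) / g[0, 0])
        c[1] = np.maximum(0.0, (b[1] - g[1, 0] * c[0] - lam / 2.0) / g[1, 1])
    return c


def _svd_extreme_init(pixels: np.ndarray) -> np.ndarray:
    """Macenko-style init: extreme angles in the top-2 singular plane."""
    # pixels: (N, 3) OD rows
    _, _, vt = np.linalg.svd(pixels, full_matrices=False)
    basis = vt[:2].T  # (3, 2)
    # orient basis vectors so projections are mostly positive
    if basis[:, 0].sum() < 0:
        basis[:, 0] *= -1
    proj = pixels @ basis  # (N, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [1, 99])
    cols = []
    for ang in (lo, hi):
        v = basis @ np.array([np.cos(ang), np.sin(ang)])
        if v.sum() < 0:
            v = -v
        cols.append(np.clip(v, 1e-6, None))
    w = np.stack(cols, axis=1)
    return w / np.linalg.norm(w, axis=0, keepdims=True)


def _as_pixels(od: np.ndarray) -> np.ndarray:
    od = np.asarray(od, dtype=float)
    if od.ndim == 3:
        return od.reshape(-1, 3)
    if od.ndim == 2 and od.shape[1] == 3:
        return od
    raise ValueError("expected an (H, W, 3) OD image or (N, 3) OD pixels")


def estimate_stain_matrix(
    od_pixels: np.ndarray,
    sparsity_lambda: float = 0.1,
    od_floor_beta: float = 0.15,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_pixels: int = 100,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Sparse-NMF estimate of the 3x2 stain matrix from OD pixels.

    Pixels whose maximum channel OD is below ``od_floor_beta`` (near-white
    background) are discarded before factorization.  Alternates an
    L1-penalized non-negative coding step with a multiplicative
    dictionary update until the relative objective decrease drops below
    ``tol``.  Columns are returned unit-norm, hematoxylin first; the
    labeling is independent of the column order of ``init`` (default:
    SVD-plane extreme-angle initialization).
    """
    if sparsity_lambda < 0 or od_floor_beta < 0:
        raise ValueError("sparsity_lambda and od_floor_beta must be >= 0")
    pixels = _as_pixels(od_pixels)
    pixels = pixels[pixels.max(axis=1) >= od_floor_beta]
    if pixels.shape[0] < min_pixels:
        raise InsufficientStainError(
            f"insufficient stained pixels ({pixels.shape[0]} < {min_pixels})"
        )
    a = pixels.T  # (3, N)
    w = np.asarray(init, dtype=float).copy() if init is not None else _svd_extreme_init(pixels)
    prev_obj = np.inf
    c = None
    for _ in range(max_iter):
        c = _coordinate_descent(a, w, sparsity_lambda, n_iter=25, c0=c)
        # multiplicative dictionary update keeps W >= 0
        num = a @ c.T
        den = w @ (c @ c.T) + 1e-12
        w = w * (num / den)
        norms = np.linalg.norm(w, axis=0, keepdims=True)
        norms[norms < 1e-12] = 1.0
        w = w / norms
        c = c * norms.T  # keep W @ C invariant across the renormalization
        resid = a - w @ c
        obj = float(np.sum(resid * resid) + sparsity_lambda * np.sum(c))
        if prev_obj - obj < tol * max(prev_obj, 1e-12):
            break
        prev_obj = obj
    # L1 shrinkage of the codes tilts the dictionary; a short unpenalized
    # polish of W in the converged basin removes that bias
    for _ in range(20):
        c = _coordinate_descent(a, w, 0.0, n_iter=30, c0=c)
        w = w * ((a @ c.T) / (w @ (c @ c.T) + 1e-12))
        norms = np.linalg.norm(w, axis=0, keepdims=True)
        norms[norms < 1e-12] = 1.0
        w = w / norms
        c = c * norms.T
    if _angle_deg(w[:, 0], w[:, 1]) < 1.0:
        raise StainDegeneracyError("estimated stain directions are collinear")
    return hematoxylin_first(w)


def solve_concentrations(
    od_pixels: np.ndarray, w: np.ndarray, sparsity_lambda: float = 0.0
) -> np.ndarray:
    """Per-pixel non-negative (optionally L1-penalized) coding under W.

    Returns C with shape (2, N).  With ``sparsity_lambda == 0`` this is
    exactly non-negative least squares.
    """
    if sparsity_lambda < 0:
        raise ValueError("sparsity_lambda must be >= 0")
    w = np.asarray(w, dtype=float)
    if w.shape != (3, 2):
        raise ValueError("W must be 3x2")
    a = _as_pixels(od_pixels).T
    return _coordinate_descent(a, w, sparsity_lambda, n_iter=120)


@dataclass
class NormalizationTarget:
    """Training-set stain target: mean stain matrix + robust scales."""

    W_target: np.ndarray  # (3, 2) unit columns, hematoxylin first
    scale_target: np.ndarray  # (2,) 99th-percentile concentrations
    percentile: float = 99.0

    def __post_init__(self):
        self.W_target = np.asarray(self.W_target, dtype=float)
        self.scale_target = np.asarray(self.scale_target, dtype=float)
        if np.any(self.scale_target <= 0):
            raise ValueError("scale_target must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "W_target": self.W_target.tolist(),
                "scale_target": self.scale_target.tolist(),
                "percentile": self.percentile,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationTarget":
        d = json.loads(text)
        return cls(
            np.array(d["W_target"]), np.array(d["scale_target"]), d.get("percentile", 99.0)
        )


@dataclass
class StainConfig:
    sparsity_lambda: float = 0.1
    od_floor_beta: float = 0.15
    max_iter: int = 200
    tol: float = 1e-6
    percentile: float = 99.0
    I0: float = I0_DEFAULT


def fit_normalization_target(
    training_slides: list[np.ndarray],
    tiles_per_slide: int = 100,
    seed: int = 0,
    config: StainConfig | None = None,
    annotations: list[np.ndarray | None] | None = None,
    estimator=None,
) -> NormalizationTarget:
    """Average per-tile stain vectors over the training set.

    For every training slide, ``tiles_per_slide`` random tiles are drawn
    (tissue-masked), a stain matrix is estimated per tile, and the unit
    column vectors are averaged arithmetically and renormalized.  The
    concentration scale is the pooled 99th percentile per stain under the
    averaged matrix.
    """
    if not training_slides:
        raise ValueError("need at least one training slide")
    cfg = config or StainConfig()
    if estimator is None:

        def estimator(od):
            return estimate_stain_matrix(
                od, cfg.sparsity_lambda, cfg.od_floor_beta, cfg.max_iter, cfg.tol
            )

    columns: list[np.ndarray] = []
    od_samples: list[np.ndarray] = []
    n_used = 0
    for idx, slide in enumerate(training_slides):
        annotation = annotations[idx] if annotations else None
        try:
            mask = tiling.tissue_mask(slide, annotation)
            tiles = tiling.sample_tiles(
                slide,
                mask,
                tiles_per_slide,
                seed=child_seed(seed, "target", idx),
                slide_id=f"train{idx}",
            )
        except tiling.InsufficientTissueError:
            log.warning("skipping training slide %d: insufficient tissue", idx)
            continue
        for tile in tiles:
            od = rgb_to_od(tile.pixels, cfg.I0)
            try:
                w = estimator(od)
            except (InsufficientStainError, StainDegeneracyError):
                continue
            columns.append(w)
            od_samples.append(od.reshape(-1, 3)[:: max(1, tile.pixels.size // (64 * 3))])
        n_used += 1
    if not columns or n_used == 0:
        raise InsufficientStainError("no training slide yielded a stain estimate")
    w_mean = np.mean(np.stack(columns), axis=0)
    w_target = hematoxylin_first(w_mean / np.linalg.norm(w_mean, axis=0, keepdims=True))
    pooled = np.concatenate(od_samples, axis=0)
    conc = solve_concentrations(pooled, w_target)
    scale = np.percentile(conc, cfg.percentile, axis=1)
    scale = np.maximum(scale, 1e-6)
    return NormalizationTarget(w_target, scale, cfg.percentile)


def target_from_tile(
    tile: tiling.Tile | np.ndarray, config: StainConfig | None = None
) -> NormalizationTarget:
    """Normalization target taken from a single tile's own stain statistics."""
    cfg = config or StainConfig()
    pixels = tile.pixels if isinstance(tile, tiling.Tile) else tile
    od = rgb_to_od(pixels, cfg.I0)
    w = estimate_stain_matrix(
        od, cfg.sparsity_lambda, cfg.od_floor_beta, cfg.max_iter, cfg.tol
    )
    conc = solve_concentrations(od, w)
    scale = np.maximum(np.percentile(conc, cfg.percentile, axis=1), 1e-6)
    return NormalizationTarget(w, scale, cfg.percentile)


def normalize_od(
    od: np.ndarray,
    target: NormalizationTarget,
    w_src: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core recomposition step on an OD image; returns (OD', C_src, C_scaled).

    Each stain row of the source concentrations is rescaled by a single
    positive factor (target robust scale over source robust scale), so
    per-pixel concentration ranks within each stain are exactly
    preserved.
    """
    conc = solve_concentrations(od, w_src)
    p_src = np.percentile(conc, target.percentile, axis=1)
    ratio = np.where(p_src > 1e-6, target.scale_target / np.maximum(p_src, 1e-6), 1.0)
    conc_scaled = conc * ratio[:, None]
    od_new = (target.W_target @ conc_scaled).T.reshape(od.shape)
    return od_new, conc, conc_scaled


def normalize_tile(
    tile: tiling.Tile | np.ndarray,
    target: NormalizationTarget,
    config: StainConfig | None = None,
    source_matrix: np.ndarray | None = None,
) -> tiling.Tile | np.ndarray:
    """Structure-preserving recomposition of a tile in the target basis.

    The tile's own stain matrix is estimated (or taken from
    ``source_matrix``, e.g. a pooled per-slide estimate), concentrations
    are solved in that basis, each stain row is rescaled to match the
    target's robust concentration scale, and the image is recomposed with
    the target matrix.  Pixel ranks within each stain are untouched.
    Tiles with too few stained pixels are returned unchanged (warned).
    """
    cfg = config or StainConfig()
    pixels = tile.pixels if isinstance(tile, tiling.Tile) else tile
    od = rgb_to_od(pixels, cfg.I0)
    try:
        w_src = (
            np.asarray(source_matrix, dtype=float)
            if source_matrix is not None
            else estimate_stain_matrix(
                od, cfg.sparsity_lambda, cfg.od_floor_beta, cfg.max_iter, cfg.tol
            )
        )
    except (InsufficientStainError, StainDegeneracyError) as exc:
        log.warning("normalize_tile: %s; returning tile unchanged", exc)
        return tile
    od_new, _, _ = normalize_od(od, target, w_src)
    out = od_to_rgb(od_new, cfg.I0)
    if isinstance(tile, tiling.Tile):
        return tiling.Tile(
            pixels=out,
            origin=tile.origin,
            slide_id=tile.slide_id,
            patient_id=tile.patient_id,
            batch=tile.batch,
            label=tile.label,
        )
    return out
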