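"""Weakly supervised tile scorer and median slide-level aggregation.

Every tile inherits its slide's Met+/Met- outcome label; a small
convolutional network maps a 224x224 RGB tile to a sigmoid score in
(0, 1), trained with binary cross-entropy, and a slide's progression-risk
score is the median of its tile scores.

The default backbone is a compact three-block CNN (stride-2 3x3
convolutions, global average pooling, linear head) sized to train on a
single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, tiling
from ._rng import child_seed, rng_from


@dataclass
class ScorerConfig:
    backbone: str = "small_cnn"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    channels: tuple[int, int, int] = (8, 16, 32)
    input_size: int = tiling.CROP_SIZE

    def __post_init__(self):
        if self.backbone != "small_cnn":
            raise ValueError(
                "only the 'small_cnn' backbone is available in this build"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class SlidePrediction:
    slide_id: str
    patient_id: int
    batch: str
    label: int
    tile_scores: np.ndarray
    slide_score: float

    def __post_init__(self):
        self.tile_scores = np.asarray(self.tile_scores, dtype=float)
        if self.tile_scores.size == 0:
            raise ValueError("tile_scores must be non-empty")


def _to_input(pixels: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 HWC in [-0.5, 0.5]."""
    return pixels.astype(np.float32) / 255.0 - 0.5


class TileScorer:
    """Three conv blocks + global average pooling + linear + sigmoid."""

    def __init__(self, config: ScorerConfig):
        self.config = config
        rng = rng_from(config.seed, "weights")
        c1, c2, c3 = config.channels
        self.net = nn.Sequential(
            nn.Conv2d(3, c1, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(c1, c2, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(c2, c3, stride=2, rng=rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(c3, 1, rng=rng),
            input_grad=False,
        )
        self.fitted = False
        self.loss_log: list[float] = []

    def logits(self, batch: np.ndarray, train: bool = False):
        out, caches = self.net.forward(batch, train=train)
        return out[:, 0], caches

    def score_batch(self, pixels_list: list[np.ndarray]) -> np.ndarray:
        x = np.stack([_to_input(p) for p in pixels_list])
        z, _ = self.logits(x, train=False)
        return np.clip(nn.sigmoid(z.astype(np.float64)), 1e-7, 1 - 1e-7)


def train_scorer(
    training_tiles: list[tiling.Tile],
    config: ScorerConfig | None = None,
    labels: np.ndarray | None = None,
) -> TileScorer:
    """Fit the tile scorer on slide-labelled tiles.

    Labels default to each tile's inherited slide label.  Augmentation
    (right-angle rotation, flips, random 224 crop) is re-drawn every
    epoch from seeded streams; the whole run is deterministic under
    ``config.seed``.
    """
    config = config or ScorerConfig()
    y = (
        np.asarray(labels, dtype=np.float32)
        if labels is not None
        else np.array([t.label for t in training_tiles], dtype=np.float32)
    )
    if len(training_tiles) != y.size or y.size == 0:
        raise ValueError("tiles and labels must be non-empty and aligned")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both outcome classes")

    scorer = TileScorer(config)
    opt = nn.Adam(scorer.net.params, lr=config.learning_rate)
    order_rng = rng_from(config.seed, "order")
    n = y.size
    for epoch in range(config.epochs):
        order = order_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    _to_input(
                        tiling.augment_tile(
                            training_tiles[i], child_seed(config.seed, "aug", epoch, int(i))
                        )
                    )
                    for i in idx
                ]
            )
            z, caches = scorer.logits(batch, train=True)
            loss, dz = nn.bce_with_logits(z, y[idx])
            opt.zero_grad()
            grad = np.zeros((idx.size, 1), dtype=np.float32)
            grad[:, 0] = dz
            scorer.net.backward(caches, grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        scorer.loss_log.append(epoch_loss / max(n_batches, 1))
    scorer.fitted = True
    return scorer


def score_tiles(scorer: TileScorer, tiles: list[tiling.Tile]) -> np.ndarray:
    """Sigmoid scores in (0,1), input order preserved, center-cropped."""
    if not scorer.fitted:
        raise ValueError("scorer is not fitted")
    if not tiles:
        return np.empty(0)
    out = []
    batch_size = 32
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start : start + batch_size]
        out.append(scorer.score_batch([tiling.center_crop(t) for t in chunk]))
    return np.concatenate(out)


def slide_score(tile_scores) -> float:
    """Median of a slide's tile scores (even length: mean of middles)."""
    scores = np.asarray(tile_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("tile_scores must be non-empty")
    return float(np.median(scores))


def predict_slide(
    scorer: TileScorer,
    tiles: list[tiling.Tile],
    slide_id: str = "",
    patient_id: int = -1,
    batch: str = "",
    label: int = -1,
) -> SlidePrediction:
    scores = score_tiles(scorer, tiles)
    return SlidePrediction(
        slide_id=slide_id or (tiles[0].slide_id if tiles else ""),
        patient_id=patient_id if patient_id >= 0 else (tiles[0].patient_id if tiles else -1),
        batch=batch or (tiles[0].batch if tiles else ""),
        label=label if label >= 0 else (tiles[0].label if tiles else -1),
        tile_scores=scores,
        slide_score=slide_score(scores),
    )
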