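"""Scaled-down cycle-consistent generative stain normalizer.

Two fully convolutional generators translate unpaired tiles between a
source domain (one test slide) and a reference domain (the training
set), trained with least-squares adversarial losses from two patch
discriminators plus an L1 cycle-consistency penalty.  The design is a
miniature of the usual unpaired image-translation recipe: 64x64 training
crops, instance-normalized small generators with a global residual skip
(near-identity at initialization), and a fixed optimizer-step budget.

Because the generators are fully convolutional they are applied to
full-size tiles directly at inference time, so no seam-prone tiled
application is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn, tiling
from ._rng import rng_from


@dataclass
class GanConfig:
    steps: int = 2000
    learning_rate: float = 2e-4
    cycle_weight: float = 10.0
    crop_size: int = 64
    batch_size: int = 2
    ngf: int = 8  # generator base channels
    ndf: int = 8  # discriminator base channels
    seed: int = 0
    log_every: int = 50


def _build_generator(ngf: int, rng) -> nn.Sequential:
    """Residual body; the final conv is near-zero so G starts ~identity."""
    return nn.Sequential(
        nn.Conv2d(3, ngf, rng=rng),
        nn.InstanceNorm(ngf),
        nn.ReLU(),
        nn.Conv2d(ngf, 2 * ngf, stride=2, rng=rng),
        nn.InstanceNorm(2 * ngf),
        nn.ReLU(),
        nn.Conv2d(2 * ngf, 2 * ngf, rng=rng),
        nn.InstanceNorm(2 * ngf),
        nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2d(2 * ngf, ngf, rng=rng),
        nn.InstanceNorm(ngf),
        nn.ReLU(),
        nn.Conv2d(ngf, 3, rng=rng, weight_scale=0.002),
    )


def _build_discriminator(ndf: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(3, ndf, stride=2, rng=rng),
        nn.LeakyReLU(),
        nn.Conv2d(ndf, 2 * ndf, stride=2, rng=rng),
        nn.LeakyReLU(),
        nn.Conv2d(2 * ndf, 1, rng=rng),
    )


def _gen_forward(gen: nn.Sequential, x: np.ndarray, train=True):
    body, caches = gen.forward(x, train=train)
    return x + body, caches  # global residual skip


def _to_signed(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float32) / 127.5 - 1.0


def _to_uint8(x: np.ndarray) -> np.ndarray:
    arr = (np.clip(x, -1.0, 1.0) + 1.0) * 127.5
    return np.rint(arr).astype(np.uint8)


class GenerativeNormalizer:
    """forward/backward mappers plus discriminators for both domains."""

    def __init__(self, config: GanConfig):
        self.config = config
        rng = rng_from(config.seed, "gan-weights")
        self.g_forward = _build_generator(config.ngf, rng)  # source -> reference
        self.g_backward = _build_generator(config.ngf, rng)  # reference -> source
        self.d_source = _build_discriminator(config.ndf, rng)
        self.d_reference = _build_discriminator(config.ndf, rng)
        self.fitted = False
        self.history: list[dict] = []

    def map_tile(self, tile: tiling.Tile | np.ndarray) -> tiling.Tile | np.ndarray:
        pixels = tile.pixels if isinstance(tile, tiling.Tile) else tile
        x = _to_signed(pixels)[None]
        y, _ = _gen_forward(self.g_forward, x, train=False)
        out = _to_uint8(y[0])
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


def _sample_crops(tiles, rng, batch, crop) -> np.ndarray:
    out = np.empty((batch, crop, crop, 3), dtype=np.float32)
    for i in range(batch):
        t = tiles[int(rng.integers(len(tiles)))]
        pixels = t.pixels if isinstance(t, tiling.Tile) else t
        h, w = pixels.shape[:2]
        r = int(rng.integers(h - crop + 1))
        c = int(rng.integers(w - crop + 1))
        out[i] = _to_signed(pixels[r : r + crop, c : c + crop])
    return out


def _lsgan_loss(pred: np.ndarray, target: float):
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 * diff / diff.size).astype(np.float32)


def _l1_loss(a: np.ndarray, b: np.ndarray):
    diff = a - b
    loss = float(np.mean(np.abs(diff)))
    return loss, (np.sign(diff) / diff.size).astype(np.float32)


def train_generative_normalizer(
    source_tiles: list,
    reference_tiles: list,
    config: GanConfig | None = None,
    seed: int | None = None,
) -> GenerativeNormalizer:
    """Adversarial + cycle training on unpaired crops for a fixed budget.

    ``steps <= 0`` returns the identity-initialized, unfitted normalizer
    with a warning.  All randomness (weights, crop sampling) is seeded.
    """
    config = config or GanConfig()
    if seed is not None:
        config = GanConfig(**{**config.__dict__, "seed": seed})
    if not source_tiles or not reference_tiles:
        raise ValueError("both tile lists must be non-empty")
    norm = GenerativeNormalizer(config)
    if config.steps <= 0:
        warnings.warn("steps <= 0: returning an identity-initialized, unfitted normalizer")
        return norm

    rng = rng_from(config.seed, "gan-crops")
    g_params = norm.g_forward.params + norm.g_backward.params
    d_params = norm.d_source.params + norm.d_reference.params
    opt_g = nn.Adam(g_params, lr=config.learning_rate, beta1=0.5)
    opt_d = nn.Adam(d_params, lr=config.learning_rate, beta1=0.5)

    for step in range(config.steps):
        x = _sample_crops(source_tiles, rng, config.batch_size, config.crop_size)
        y = _sample_crops(reference_tiles, rng, config.batch_size, config.crop_size)

        fake_y, cache_gf = _gen_forward(norm.g_forward, x)
        fake_x, cache_gb = _gen_forward(norm.g_backward, y)

        # --- discriminator update (generator outputs detached) ---
        opt_d.zero_grad()
        d_loss = 0.0
        for disc, real, fake in (
            (norm.d_reference, y, fake_y),
            (norm.d_source, x, fake_x),
        ):
            pr, c_real = disc.forward(real)
            lr_, gr = _lsgan_loss(pr, 1.0)
            disc.backward(c_real, gr)
            pf, c_fake = disc.forward(fake)
            lf, gf = _lsgan_loss(pf, 0.0)
            disc.backward(c_fake, gf)
            d_loss += lr_ + lf
        opt_d.step()

        # --- generator update ---
        opt_g.zero_grad()
        rec_x, cache_fb = _gen_forward(norm.g_backward, fake_y)
        rec_y, cache_ff = _gen_forward(norm.g_forward, fake_x)

        p_fy, c_dfy = norm.d_reference.forward(fake_y)
        adv_f, g_adv_fy = _lsgan_loss(p_fy, 1.0)
        p_fx, c_dfx = norm.d_source.forward(fake_x)
        adv_b, g_adv_fx = _lsgan_loss(p_fx, 1.0)
        cyc_x, g_cyc_x = _l1_loss(rec_x, x)
        cyc_y, g_cyc_y = _l1_loss(rec_y, y)
        lam = config.cycle_weight

        # path: cycle loss on rec_x -> back through g_backward -> fake_y
        grad_fake_y = norm.g_backward.backward(cache_fb, lam * g_cyc_x)
        # the residual skip of g_backward passes the cycle grad straight through
        grad_fake_y = grad_fake_y + lam * g_cyc_x
        # adversarial branch through the (frozen-for-this-purpose) critic
        grad_fake_y = grad_fake_y + norm.d_reference.backward(c_dfy, g_adv_fy)
        gx = norm.g_forward.backward(cache_gf, grad_fake_y)

        grad_fake_x = norm.g_forward.backward(cache_ff, lam * g_cyc_y)
        grad_fake_x = grad_fake_x + lam * g_cyc_y
        grad_fake_x = grad_fake_x + norm.d_source.backward(c_dfx, g_adv_fx)
        gy = norm.g_backward.backward(cache_gb, grad_fake_x)
        del gx, gy
        # discard critic-parameter gradients accumulated on the generator pass
        for p in d_params:
            p.grad[...] = 0.0
        opt_g.step()

        if step % config.log_every == 0 or step == config.steps - 1:
            norm.history.append(
                {
                    "step": step,
                    "d_loss": d_loss,
                    "g_adv": adv_f + adv_b,
                    "g_cycle": cyc_x + cyc_y,
                }
            )
    norm.fitted = True
    return norm


def apply_generative_normalizer(
    normalizer: GenerativeNormalizer, tile: tiling.Tile | np.ndarray
) -> tiling.Tile | np.ndarray:
    """Map one tile through the forward generator (full-tile, clipped)."""
    return normalizer.map_tile(tile)
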