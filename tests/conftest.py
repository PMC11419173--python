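"""Shared fixtures: one small rendered cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import stainshift as ss


@pytest.fixture(scope="session")
def profiles():
    """Noise-free, jitter-free batch profiles (exact optical ground truth)."""
    p_a, p_b = ss.default_profiles(rotation_deg=15.0, intensity_ratio=0.6, noise_sd=0.0)
    from dataclasses import replace

    return (
        replace(p_a, slide_rotation_sd=0.0, slide_intensity_log_sd=0.0),
        replace(p_b, slide_rotation_sd=0.0, slide_intensity_log_sd=0.0),
    )


@pytest.fixture(scope="session")
def patient():
    return ss.sample_cohort(4, 0.5, 0.5, seed=11)[0]


@pytest.fixture(scope="session")
def pair(patient, profiles):
    return ss.make_batch_pair(patient, profiles[0], profiles[1], 768, 768, seed=5)


@pytest.fixture(scope="session")
def slide_a(pair):
    return pair.slide_A


@pytest.fixture(scope="session")
def mask_a(slide_a):
    return ss.tissue_mask(slide_a)


@pytest.fixture(scope="session")
def tiles_a(slide_a, mask_a):
    return ss.sample_tiles(slide_a, mask_a, 8, seed=3, slide_id="A0", label=0)


@pytest.fixture(scope="session")
def tile_a(tiles_a):
    return tiles_a[0]


@pytest.fixture(scope="session")
def labelled_tiles():
    """Small two-class tile set with a strong planted texture signal."""
    patients = ss.sample_cohort(8, 0.5, 0.8, seed=21)
    p_a, _ = ss.default_profiles(noise_sd=0.02)
    tiles = []
    for p in patients:
        conc = ss.synthesize_concentration_fields(p, 640, 640)
        img = ss.render_rgb(conc, p_a, seed=300 + p.patient_id)
        mask = ss.tissue_mask(img)
        tiles += ss.sample_tiles(
            img,
            mask,
            12,
            seed=p.patient_id,
            slide_id=f"s{p.patient_id}",
            patient_id=p.patient_id,
            label=p.label,
        )
    return tiles
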