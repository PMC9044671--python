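"""Shared fixtures: easy synthetic tiles and a small cross-variant benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from bollseg import models, synthetic, tiling, training

EASY_KWARGS = dict(
    film_glare_fraction=0.0,
    branch_density=0.0,
    illumination_jitter=0.02,
)


def make_easy_tiles(n: int, seed: int, size: int = 64,
                    ratio_range: tuple[float, float] = (0.05, 0.40)):
    """High-contrast scenes (no glare, no occluders): a learnable benchmark."""
    ss = np.random.SeedSequence(seed).spawn(n)
    rng = np.random.default_rng(seed)
    tiles = []
    for child in ss:
        cfg = synthetic.SceneConfig(
            width=size,
            height=size,
            target_boll_ratio=float(rng.uniform(*ratio_range)),
            seed=int(child.generate_state(1)[0] % 2**31),
            **EASY_KWARGS,
        )
        tiles.append(synthetic.generate_scene(cfg))
    return tiles


@pytest.fixture(scope="session")
def easy_tiles_small():
    """8 easy 32x32 tiles for fast train-loop plumbing tests."""
    return make_easy_tiles(8, seed=11, size=32)


@pytest.fixture(scope="session")
def variant_benchmark():
    """Train all five architectures on one small easy benchmark.

    64 tiles, 80/20 split, 5 epochs, batch 8, base_width 16 — shared by the
    loss-trend and dilation-comparison checks so the models are trained once
    per session.
    """
    tiles = make_easy_tiles(64, seed=7)
    split = tiling.split_dataset(tiles, 0.8, seed=0)
    config = training.TrainConfig(epochs=5, batch_size=8, seed=0)
    results = {}
    for variant in models.VARIANTS:
        model = models.build_model(models.make_spec(variant, base_width=16), seed=0)
        results[variant] = training.train(model, split, config)
    return results
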