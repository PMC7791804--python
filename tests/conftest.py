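"""Shared fixtures: a desk-scale chain and one fully processed synthetic scene."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from pulsemaps import (
    ChainConfig,
    FilterConfig,
    PoolingConfig,
    SceneConfig,
    SpectralConfig,
    generate_scene,
    run_chain,
    scene_ground_truth,
)


@pytest.fixture(scope="session")
def desk_pooling() -> PoolingConfig:
    """Small pooling kernel so scenes stay desk-sized while exercising both stages."""
    return PoolingConfig(sigma_gauss=2.0, n_kernel=9, d_x=2, d_y=2, center=True)


@pytest.fixture(scope="session")
def desk_chain(desk_pooling) -> ChainConfig:
    """Adult heart-band chain on the desk-scale ROI lattice."""
    return ChainConfig(
        pooling=desk_pooling,
        filter=FilterConfig(f_low=0.80, f_high=5.0, order=6, t_seg=10.0),
        spectral=SpectralConfig(f_band_low=0.85, f_band_high=3.98, n_fft=1024),
    )


@pytest.fixture(scope="session")
def scene_run(desk_chain):
    """One silhouette scene processed end to end, with ground truth."""
    cfg = SceneConfig(seed=1)
    seq = generate_scene(cfg)
    banks = run_chain(seq, desk_chain)
    gt = scene_ground_truth(cfg, desk_chain.pooling)
    return SimpleNamespace(scene=cfg, seq=seq, chain=desk_chain, bank=banks[0], gt=gt)
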