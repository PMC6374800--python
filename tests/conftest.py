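"""Shared fixtures: phantoms and cached full-pipeline results."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from urseg.dptrace import segment_image
from urseg.phantom import PhantomParams, generate_phantom, generate_suite

SUITE_N = 20
SUITE_SEED = 1


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free, texture-free phantom: piecewise-constant levels."""
    return generate_phantom(
        PhantomParams(
            seed=2, noise_sigma=0.0, edge_blur=0.0, skin_blur=0.0,
            soft_texture=0.0, bone_texture=0.0, bg_gradient=0.0, collimation=0,
        )
    )


@pytest.fixture(scope="session")
def phantom_suite():
    return generate_suite(SUITE_N, master_seed=SUITE_SEED)


@pytest.fixture(scope="session")
def segmented_suite(phantom_suite):
    """Full-pipeline results for every suite phantom (the expensive fixture)."""
    results = []
    for truth in phantom_suite:
        contours, inter = segment_image(truth.image, return_intermediate=True)
        results.append((truth, contours, inter))
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_params(**kwargs) -> PhantomParams:
    return replace(PhantomParams(), **kwargs)
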