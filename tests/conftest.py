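"""Shared fixtures: small deterministic synthetic scenes."""

import pytest

from phasetag import SceneParams, generate_scene


def clean_scene_params(**overrides) -> SceneParams:
    """Noise-free, blur-free scene parameters for exact-arithmetic tests."""
    base = dict(
        image_shape=(256, 256),
        n_cells=8,
        psf_sigma=0.0,
        poisson_gain=None,
        read_noise_sigma=0.0,
        background_intensity=0.0,
        cytoplasm_intensity=100.0,
        condensate_fraction=1.0,
        partition_ratio=2.0,
        seed=2,
    )
    base.update(overrides)
    return SceneParams(**base)


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free scene: 8 cells, all carrying a rho=2 condensate."""
    return generate_scene(clean_scene_params())


@pytest.fixture(scope="session")
def noisy_scene():
    """A default-noise scene with a 50% condensate-carrying fraction."""
    params = SceneParams(
        image_shape=(512, 512), n_cells=40, partition_ratio=1.6,
        condensate_fraction=0.5, seed=3,
    )
    return generate_scene(params)
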