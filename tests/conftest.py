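import numpy as np
import pytest

from peroxiquant.scene import SceneSpec, generate_scene


def ring_scene_spec(offset_deg: float, seed: int = 11, n: int = 20,
                    size: int = 448) -> SceneSpec:
    """Two-color ring-organelle scene sized so every organelle fits a region."""
    return SceneSpec(
        image_size_px=(size, size),
        n_organelles=n,
        diameter_range_nm=(200.0, 340.0),
        morphology_mix={"ring": 1.0},
        domain_offset_deg=offset_deg,
        seed=seed,
        min_separation_nm=1100.0,
    )


@pytest.fixture(scope="session")
def congruent_scene():
    """Scene whose two protein channels carry domains at identical angles."""
    stack, gt = generate_scene(ring_scene_spec(0.0))
    return stack, gt


@pytest.fixture(scope="session")
def offset_scene():
    """Scene with 90° angular separation between the protein channels."""
    stack, gt = generate_scene(ring_scene_spec(90.0))
    return stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
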