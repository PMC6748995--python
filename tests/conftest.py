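import numpy as np
import pytest

from nephroquant import (
    ImageStack,
    SphereImageParams,
    generate_sphere_image,
)


@pytest.fixture(scope="session")
def default_image():
    """One default synthetic image + truth, shared across tests."""
    params = SphereImageParams(seed=11, positive_fraction=0.4856)
    return generate_sphere_image(params)


@pytest.fixture
def small_params():
    """Fast, small image for structural tests."""
    return SphereImageParams(
        image_shape=(128, 128),
        n_spheres=1,
        nuclei_per_sphere=12,
        sphere_radius=40.0,
        seed=5,
    )


def make_stack(nuclear, **markers):
    """ImageStack from plain arrays (test helper)."""
    channels = {"nuclear": np.asarray(nuclear, dtype=float)}
    channels.update({k: np.asarray(v, dtype=float) for k, v in markers.items()})
    return ImageStack(channels=channels)
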