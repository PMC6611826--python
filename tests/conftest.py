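import numpy as np
import pytest

from dropletkit import SyntheticParams


@pytest.fixture
def small_params() -> SyntheticParams:
    """A small, quick-to-render field used across tests."""
    return SyntheticParams(
        image_shape=(128, 128),
        n_droplets=12,
        poisson_counts=False,
        n_nuclei=2,
        nucleus_radius=1.2,
        seed=7,
    )


@pytest.fixture
def quiet_params(small_params) -> SyntheticParams:
    """Same field without any noise (exact-recovery scenarios)."""
    import dataclasses

    return dataclasses.replace(small_params, gaussian_sd=0.0, shot_noise_scale=0.0)


def disc_image(shape, discs, value=200.0, background=0.0):
    """Paint analytic discs (row, col, radius_px) onto a flat background."""
    img = np.full(shape, background, dtype=np.float64)
    rr, cc = np.indices(shape)
    for row, col, radius in discs:
        img[(rr - row) ** 2 + (cc - col) ** 2 <= radius**2] = value
    return img
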