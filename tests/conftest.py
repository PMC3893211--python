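import numpy as np
import pytest

from xenoscreen import AcquisitionParams, generate_scene, render_zstack


@pytest.fixture(scope="session")
def noise_free_params() -> AcquisitionParams:
    return AcquisitionParams(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def scene(noise_free_params):
    """A fixed three-migration-focus scene used across modules."""
    return generate_scene(noise_free_params, 3, [100.0, 200.0, 500.0], 2.0, seed=7)


@pytest.fixture(scope="session")
def tumor_composite(scene, noise_free_params):
    """Noise-free in-focus tumor image (focal slice of the rendered stack)."""
    stack = render_zstack(scene, noise_free_params, "tumor", 1)
    return stack.slices[noise_free_params.focus_index]


def brute_force_centroid(image: np.ndarray, threshold: float, pixel_size_um: float):
    """Independent oracle: weighted mean position over supra-threshold pixels."""
    rows, cols = np.nonzero(image > threshold)
    w = image[rows, cols]
    return (
        float((w * cols).sum() / w.sum()) * pixel_size_um,
        float((w * rows).sum() / w.sum()) * pixel_size_um,
    )
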