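import numpy as np
import pytest

from fundusmosaic.image_io import GrayImage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A compact master scene shared by tests that only need plausible structure."""
    from fundusmosaic.synthetic_fundus import generate_vessel_tree

    return generate_vessel_tree(seed=7, n_roots=4, image_size=1400)


@pytest.fixture(scope="session")
def default_pair(small_scene):
    from fundusmosaic.synthetic_fundus import make_pair

    return make_pair(small_scene, transform_kind="similarity",
                     overlap_target=0.5, seed=10_007)


@pytest.fixture(scope="session")
def vessel_run(default_pair):
    """One full vessel-pipeline run shared by the tests that inspect it."""
    from fundusmosaic.pipeline import run_vessel_pipeline

    report, result = run_vessel_pipeline(default_pair.macula_image,
                                         default_pair.onh_image)
    return default_pair, report, result


def tube_image(size: int = 128, half_width: float = 2.0, horizontal: bool = True,
               depth: float = 0.4, background: float = 0.8) -> GrayImage:
    """A single dark tube with Gaussian cross-section on a flat background."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dist = np.abs(yy - size / 2) if horizontal else np.abs(xx - size / 2)
    img = background - depth * np.exp(-dist ** 2 / (2 * half_width ** 2))
    return GrayImage(np.clip(img, 0.0, 1.0))
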