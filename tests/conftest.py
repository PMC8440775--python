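from __future__ import annotations

import numpy as np
import pytest

from redica import PreprocessedImage, scene_battery


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_images(rng):
    """Twenty random 32x32 intensity grids for oracle-equivalence checks."""
    return [rng.random((32, 32)) for _ in range(20)]


@pytest.fixture()
def as_pre():
    def _wrap(arr):
        return PreprocessedImage.from_array(np.asarray(arr, dtype=float))
    return _wrap


@pytest.fixture(scope="session")
def battery():
    """The 20-scene blob/vessel battery (lesion radii 3-12 px, one vessel,
    noise sd 0.02) used by the discrimination and monotonicity checks."""
    return scene_battery(20, master_seed=1, radius_range=(3.0, 12.0))


@pytest.fixture(scope="session")
def disc_scenes():
    """Twenty disc-localization scenes: a randomly placed line-crossed
    bright square on noisy background with small lesions, no vessels."""
    return scene_battery(20, master_seed=5, n_vessels=0,
                         radius_range=(3.0, 4.5), n_blobs=3)
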