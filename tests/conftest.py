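import logging

import numpy as np
import pytest

from ffoafuse.nsct import build_filter_banks
from ffoafuse.pipeline import train_default_dictionary
from ffoafuse.synthetic_data import make_multifocus_pair, make_vessel_phantom

# quiet the pipeline's INFO logging during the suite (tests that assert on
# logs raise the level locally via caplog)
logging.getLogger("ffoafuse").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def filter_bank():
    return build_filter_banks("pyrexc", "vk")


@pytest.fixture(scope="session")
def shared_dictionary():
    """Reduced-size default dictionary shared across fusion tests.

    128 atoms / 8 iterations / 5000 phantom patches: same construction as
    the full default, scaled down so the suite trains it once in seconds.
    """
    return train_default_dictionary(
        seed=42, n_atoms=128, n_iterations=8, n_patches=5000
    )


def textured_fusion_pair(seed: int, size: int = 256, blur_sigma: float = 3.0):
    """The canonical fusion study condition: dense textured phantom, vertical
    focus split at a seed-dependent position, complementary sigma=3 blur.

    Returns (sharp ground truth, A, B, focus mask, split column).
    """
    phantom = make_vessel_phantom(
        size, size, n_vessels=20, seed=seed, texture_amplitude=0.03
    )
    split = size // 2 + ((seed * 37) % 61) - 30
    focus = np.zeros_like(phantom, dtype=bool)
    focus[:, :split] = True
    A, B, gt = make_multifocus_pair(phantom, focus, blur_sigma=blur_sigma, seed=seed)
    return phantom, A, B, gt, split


@pytest.fixture(scope="session")
def fusion_pair_factory():
    return textured_fusion_pair
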