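"""Shared fixtures: desk-scale phantoms and small networks."""

import numpy as np
import pytest

from wmh3d.attention_unet import ModelConfig, build_network
from wmh3d.phantom import PhantomSpec, generate_phantom

# Desk-scale model: same depth as the production architecture, narrow stages.
SMALL_MODEL = dict(depth=4, base_channels=8, reduction_ratio=4)
# Tiny model for smoke tests where only the contracts matter.
TINY_MODEL = dict(depth=2, base_channels=4, reduction_ratio=2)


def phantom_slices(seeds) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the slices of several default phantoms (16 slices each)."""
    imgs, msks = [], []
    for s in seeds:
        stack, mask = generate_phantom(PhantomSpec(seed=s))
        imgs.append(stack.voxels)
        msks.append(mask.labels)
    return np.concatenate(imgs), np.concatenate(msks)


@pytest.fixture(scope="session")
def train_set():
    """32 training slices: phantoms with seeds 0 and 1."""
    return phantom_slices([0, 1])


@pytest.fixture(scope="session")
def heldout_set():
    """16 held-out slices from an unseen phantom (seed 100)."""
    return phantom_slices([100])


@pytest.fixture
def small_net():
    return build_network(ModelConfig(**SMALL_MODEL), seed=0)


@pytest.fixture
def tiny_net():
    return build_network(ModelConfig(**TINY_MODEL), seed=0)
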