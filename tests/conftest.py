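"""Shared fixtures: small deterministic volumes, operators and phantoms."""

import numpy as np
import pytest

from rigidmoco.geometry import ImageVolume
from rigidmoco.operators import RigidMotionOperator, SamplingPattern


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_shape():
    return (16, 16, 16)


@pytest.fixture(scope="session")
def random_volume(rng, small_shape):
    data = rng.standard_normal(small_shape) + 1j * rng.standard_normal(small_shape)
    return ImageVolume(data)


@pytest.fixture(scope="session")
def full_pattern(small_shape):
    return SamplingPattern.full(small_shape)


@pytest.fixture(scope="session")
def full_operator(full_pattern):
    return RigidMotionOperator(full_pattern)


@pytest.fixture(scope="session")
def gaussian_blob():
    """Band-limited, compactly supported test object (24^3, sigma 2.5)."""
    shape = (24, 24, 24)
    x = np.stack(np.meshgrid(*[np.arange(n) - n // 2 for n in shape], indexing="ij"))
    g = np.exp(-(x ** 2).sum(axis=0) / (2 * 2.5 ** 2))
    return ImageVolume(g.astype(np.complex128))
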