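import numpy as np
import pytest

from patrans import PatternMatrix, znormalise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def normal_patterns(rng, n_vox, n_stim):
    """Z-scored standard-normal pattern matrix, the study's data model."""
    return znormalise(PatternMatrix(rng.standard_normal((n_vox, n_stim))))


@pytest.fixture
def pattern_pair(rng):
    """Small independent (X, Y) pair: 6-voxel input, 5-voxel output, 10 stimuli."""
    X = normal_patterns(rng, 6, 10)
    Y = normal_patterns(rng, 5, 10)
    return X, Y
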