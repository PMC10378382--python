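import numpy as np
import pytest

from headlag.skeleton import KEYPOINTS_13, CanonicalSequence, SkeletonSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_skeleton(rng, n_frames=4, dim=3, sequence_id="seq", label=None):
    """A random (not anatomically meaningful) full-schema sequence."""
    return SkeletonSequence(
        sequence_id=sequence_id,
        coords=rng.normal(size=(n_frames, 13, dim)),
        keypoints=KEYPOINTS_13,
        label=label,
    )


def random_canonical(rng, n_frames=4, sequence_id="canon", label=None):
    return CanonicalSequence(
        sequence_id=sequence_id,
        coords=rng.uniform(size=(n_frames, 13, 2)),
        keypoints=KEYPOINTS_13,
        label=label,
    )


@pytest.fixture
def skeleton_factory(rng):
    return lambda **kw: random_skeleton(rng, **kw)
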