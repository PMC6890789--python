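import numpy as np
import pytest

from clarimap import synth


@pytest.fixture(scope="session")
def toy_atlas():
    """Depth-6 nested rectangular atlas with a synthetic projection table."""
    return synth.make_toy_atlas(synth.AtlasSpec(seed=0))


@pytest.fixture(scope="session")
def tube_phantom():
    """Straight axial tube, SNR 8, with centerline and in-tube mask."""
    return synth.make_tube_phantom(synth.TubeSpec(seed=1))


@pytest.fixture(scope="session")
def blob_phantom_small():
    """40 blobs in a small volume for fast segmentation unit tests."""
    spec = synth.BlobSpec(shape=(64, 64, 32), n_blobs=40, seed=4)
    return synth.make_blob_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
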