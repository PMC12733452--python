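import numpy as np
import pytest

from sonoseg import phantom
from sonoseg.data_io import index_dataset, load_pair, preprocess, preprocess_mask


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """4 patients x 3 slices of 64x64 phantoms in the on-disk layout."""
    root = tmp_path_factory.mktemp("phantoms")
    phantom.generate_dataset(4, 3, root, seed=7, image_size=64)
    return root


@pytest.fixture(scope="session")
def phantom_arrays(phantom_root):
    index = index_dataset(phantom_root)
    pairs = [load_pair(r) for _, r in index.iterrows()]
    images = np.stack([preprocess(p.image, 64) for p in pairs])
    masks = np.stack([preprocess_mask(p.mask, 64) for p in pairs])
    return images, masks


@pytest.fixture
def tumor_pair():
    """One deterministic noise-free phantom with a centered lesion."""
    params = phantom.PhantomParams(image_size=64, tumor_radius=8.0, texture_sd=0.0, seed=3)
    return phantom.generate_phantom(params)
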