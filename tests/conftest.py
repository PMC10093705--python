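import numpy as np
import pytest

from cytofmm import BlobSpec, generate_blobs, generate_toy_images


@pytest.fixture
def rng():
    return np.random.default_rng(20230406)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian classes in the unit square."""
    spec = BlobSpec(
        n_per_class=100,
        n_features=2,
        class_centers=((0.3, 0.3), (0.7, 0.7)),
        spread=0.05,
        seed=11,
    )
    return generate_blobs(spec)


@pytest.fixture(scope="session")
def toy_image_dir(tmp_path_factory):
    """Small rendered cell-image dataset (10 per class) with manifest."""
    root = tmp_path_factory.mktemp("toycells")
    manifest = generate_toy_images(n_per_class=10, seed=5, out_dir=root)
    return root, manifest


def random_box_pair(rng, n_dims):
    """Two random valid hyperboxes of different classes in [0,1]^n."""
    def one(cid):
        lo = rng.random(n_dims)
        hi = lo + rng.random(n_dims) * (1.0 - lo)
        from cytofmm import Hyperbox

        return Hyperbox(lo, hi, cid)

    return one(0), one(1)
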