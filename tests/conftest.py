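import numpy as np
import pytest
from hypothesis import settings

import atnquant as aq

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dictionary():
    return aq.load_label_dictionary()


@pytest.fixture(scope="session")
def masks():
    return aq.load_masks()


@pytest.fixture(scope="session")
def label_phantom(dictionary):
    return aq.make_label_phantom(aq.PhantomSpec(seed=0), dictionary)


@pytest.fixture(scope="session")
def uptake_map(dictionary):
    # amyloid-positive-like pattern with the cerebellum pinned to 1.0
    return aq.uptake_from_tissue(dictionary, gm=1.8, wm=1.3, csf=0.3,
                                 overrides={"cerebellum": 1.0,
                                            "cerebellar vermal": 1.0})


@pytest.fixture(scope="session")
def pet_phantom(label_phantom, uptake_map):
    """Noiseless, unblurred PET phantom on the label grid."""
    return aq.make_pet_phantom(label_phantom, uptake_map)


@pytest.fixture(scope="session")
def smooth_pet(label_phantom, uptake_map):
    """Smooth (4 mm PSF) noiseless phantom used for registration tests."""
    return aq.make_pet_phantom(label_phantom, uptake_map, psf_fwhm=4.0)


def tiny_dictionary(n):
    return aq.LabelDictionary(
        entries=tuple((i, f"Region {i}", "GM") for i in range(1, n + 1)))


def random_label_volume(seed, shape=(20, 20, 20), n_labels=5, voxel=2.0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
    grid = aq.SpaceSpec.isotropic(shape, voxel)
    return aq.LabelVolume(labels=labels, affine=grid.affine,
                          dictionary=tiny_dictionary(n_labels))
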