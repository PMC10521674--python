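import numpy as np
import pytest

from nphkit.spatial import build_probability_maps, probmaps_to_subject
from nphkit.synthetic import PhantomParams, make_parcellation, make_phantom, make_streamlines
from nphkit.types import AffineTransform, LabelVolume


@pytest.fixture(scope="session")
def phantom_normal():
    return make_phantom(PhantomParams(seed=0))


@pytest.fixture(scope="session")
def phantom_nph():
    return make_phantom(PhantomParams(dilation=1.8, seed=0))


@pytest.fixture(scope="session")
def parcellation90():
    return make_parcellation(90, seed=1)


@pytest.fixture(scope="session")
def streamlines500(parcellation90):
    return make_streamlines(parcellation90, 500, seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom + its own-subject probability maps (desk-scale net input)."""
    vol, lab = make_phantom(
        PhantomParams(shape=(32, 32, 32), spacing=(2.0, 2.0, 4.0), dilation=1.6, seed=3)
    )
    pm_mni = build_probability_maps([lab])
    identity = AffineTransform(np.eye(4), direction="mni_to_subject")
    pms = probmaps_to_subject(pm_mni, identity, vol)
    return vol, lab, pms


def as_mask_volume(mask, like: LabelVolume) -> LabelVolume:
    return LabelVolume(
        labels=np.asarray(mask).astype(np.uint8), legend={1: "mask"},
        spacing=like.spacing, affine=like.affine,
    )
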