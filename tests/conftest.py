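import numpy as np
import pytest

from histoatlas import phantom
from histoatlas.core import LabelVolume, Volume
from histoatlas.segment import TissueClustering


@pytest.fixture(scope="session")
def label_phantom():
    spec = phantom.PhantomSpec((32, 32, 32), n_rois=5, seed=1)
    return phantom.make_label_phantom(spec)


@pytest.fixture(scope="session")
def clustering(label_phantom):
    return TissueClustering.identity(np.unique(label_phantom.data))


@pytest.fixture(scope="session")
def intensity_model():
    return phantom.ClassIntensityModel.from_means(
        means=[20, 60, 90, 120, 150, 180], sds=[2, 3, 3, 3, 3, 3]
    )


@pytest.fixture(scope="session")
def intensity_phantom(label_phantom, intensity_model, clustering):
    return phantom.sample_intensity(
        label_phantom, intensity_model, clustering, seed=2, texture_sd=4.0
    )


@pytest.fixture(scope="session")
def big_roi_template():
    """36^3 template with three ROIs above 500 voxels (plus one small)."""
    shape = (36, 36, 36)
    lab = np.zeros(shape, np.int32)
    g = np.mgrid[0:36, 0:36, 0:36]
    geometry = [
        ((12, 12, 18), (7, 6, 6)),
        ((24, 22, 14), (6, 7, 5)),
        ((18, 26, 26), (5, 5, 6)),
        ((12, 24, 22), (4, 4, 4)),
    ]
    for i, (c, a) in enumerate(geometry):
        m = sum(((g[d] - c[d]) / a[d]) ** 2 for d in range(3)) < 1
        lab[m & (lab == 0)] = i + 1
    return LabelVolume(lab)


@pytest.fixture(scope="session")
def curved_stack():
    """Section stack over a curved tube: the banana-effect substrate."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    shape = (12, 36, 36)
    vol = np.zeros(shape)
    lab = np.zeros(shape, np.int32)
    y, x = np.mgrid[0:36, 0:36]
    for z in range(shape[0]):
        t = z / (shape[0] - 1)
        cy = 18 + 8 * (2 * t - 1) ** 2 - 4
        cx = 10 + 16 * t
        m = ((y - cy) / 5) ** 2 + ((x - cx) / 4) ** 2 < 1
        vol[z][m] = 150
        lab[z][m] = 1
        m2 = ((y - (34 - cy)) / 4) ** 2 + ((x - cx) / 3.5) ** 2 < 1
        vol[z][m2] = 80
        lab[z][m2] = 2
    tex = ndimage.gaussian_filter(rng.normal(size=shape), (0, 1.5, 1.5))
    vol = vol + 12 * tex / tex.std() + 30
    return phantom.make_section_stack(
        Volume(vol), LabelVolume(lab), 6, {"rigid": 1.0, "bspline": 0.8}, seed=3
    )
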