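import numpy as np
import pytest

from peridce import PhantomSpec, RoiBox, generate_phantom

# ROI boxes used for the default phantom geometry: the tumour box surrounds
# the tumour plus its four shells with margin and stays inside the breast;
# the healthy box covers FGT, adipose, skin and a sliver of air.
TUMOUR_BOX = RoiBox(y_range=(26, 54), x_range=(44, 74), z_range=(12, 29))
HEALTHY_BOX = RoiBox(y_range=(24, 56), x_range=(2, 38), z_range=(4, 36))


@pytest.fixture(scope="session")
def default_phantom():
    """One rasterised phantom shared by read-only tests."""
    spec = PhantomSpec(seed=7)
    series, truth = generate_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(seed=7, noise_sd=0.0)
    series, truth = generate_phantom(spec)
    return spec, series, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
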