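import numpy as np
import pytest

import pelvimetry3d as p
from pelvimetry3d import calibration


@pytest.fixture(scope="session")
def female_template():
    lset, report = p.build_template(
        {m: v[0] for m, v in calibration.FEMALE_TARGETS.items()}, seed=0
    )
    return lset, report


@pytest.fixture(scope="session")
def male_template():
    lset, report = p.build_template(
        {m: v[0] for m, v in calibration.MALE_TARGETS.items()}, seed=0
    )
    return lset, report


@pytest.fixture(scope="session")
def female_phantom(female_template):
    """Default-condition phantom: 2 mm isotropic, CT-like noise."""
    lset, _ = female_template
    return p.rasterize_phantom(lset, spacing=(2.0, 2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def female_phantom_clean(female_template):
    """Noise-free two-valued phantom, for exact-threshold oracles."""
    lset, _ = female_template
    return p.rasterize_phantom(lset, spacing=(2.0, 2.0, 2.0), noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def phantom_mesh(female_phantom):
    seeds = p.suggest_bone_seeds(female_phantom, 500.0)
    mask = p.segment_volume(female_phantom, seeds, tolerance=500.0)
    return p.extract_surface(mask)
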