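import numpy as np
import pytest

import luxpaper as lp

NACLO_CALIBRATORS = [0.0, 0.1, 0.5, 1.0, 2.0, 4.0]


@pytest.fixture(scope="session")
def naclo_model():
    """NaClO-like inhibition: midpoint mid-range of the 0.1-4.0 ppm calibrators."""
    return lp.InhibitionModel(top=100.0, bottom=0.0, ec50=1.0, hill=1.5)


@pytest.fixture(scope="session")
def camera():
    return lp.get_camera("oneplus6")


@pytest.fixture(scope="session")
def quiet_camera(camera):
    """Noise-free variant for analytic expectations."""
    return camera.with_(shot_noise=False, read_noise_adu=0.0)


@pytest.fixture(scope="session")
def flower_fixture(naclo_model, camera):
    """One spiked flower-sensor image with ground truth (seeded)."""
    img, layout, record = lp.make_assay_fixture(
        "NaClO", NACLO_CALIBRATORS, 1.0, naclo_model, camera, seed=11, cv=0.05
    )
    return img, layout, record


@pytest.fixture(scope="session")
def noiseless_flower(naclo_model, quiet_camera):
    img, layout, record = lp.make_assay_fixture(
        "NaClO", NACLO_CALIBRATORS, 1.0, naclo_model, quiet_camera, seed=5
    )
    return img, layout, record
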