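import numpy as np
import pytest

import fiberwall as fw


@pytest.fixture(scope="session")
def structural() -> fw.StructuralConstants:
    """Mid-cohort structural constants (alpha=45 deg, typical dispersions)."""
    return fw.StructuralConstants.from_degrees(45.0, 0.16, 0.42)


@pytest.fixture(scope="session")
def protocols():
    return fw.make_protocols(1.3, 1.3, n_steps=50)


@pytest.fixture(scope="session")
def two_fiber_truth() -> fw.TwoFiberParams:
    """Ground-truth two-fiber parameters at cohort-typical magnitudes."""
    return fw.TwoFiberParams(c2=15.0, k1=12.0, k2=3.5)


@pytest.fixture(scope="session")
def noise_free_dataset(two_fiber_truth, structural, protocols) -> fw.BiaxialDataset:
    return fw.simulate_biaxial(two_fiber_truth, structural, protocols)


@pytest.fixture(scope="session")
def table2():
    return fw.load_table2()


@pytest.fixture(scope="session")
def table1():
    return fw.load_table1()


def grating_image(angle_deg: float, size: int = 256, freq: float = 0.06,
                  pixels_only: bool = False):
    """Sinusoidal grating whose stripes (fiber direction) lie at ``angle_deg``
    counterclockwise from the horizontal axis; wave vector perpendicular."""
    ang = np.deg2rad(angle_deg)
    r, c = np.mgrid[0:size, 0:size].astype(float)
    x, y = c, -r  # y-up frame
    phase = 2.0 * np.pi * freq * (-x * np.sin(ang) + y * np.cos(ang))
    px = 0.5 + 0.5 * np.cos(phase)
    return px if pixels_only else fw.TextureImage(px)
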