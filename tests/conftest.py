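import numpy as np
import pytest

import carodop as cd


@pytest.fixture(scope="session")
def geom():
    return cd.ProbeGeometry()


@pytest.fixture(scope="session")
def cfg():
    return cd.AcquisitionConfig()


@pytest.fixture(scope="session")
def phantom_sequence():
    """One seeded speckle phantom sequence with known lumen truth."""
    truth = cd.PhantomTruth(center_x=2.0, center_y=23.0, radius=3.0, seed=42)
    return cd.make_phantom_sequence(truth), truth


@pytest.fixture(scope="session")
def steady_acquisition(geom, cfg):
    """One full synthetic acquisition: steady 34 cm/s parabolic flow, SNR 20 dB."""
    flow = cd.steady_flow(0.34, 3.0)
    phantom = cd.PhantomTruth(center_x=0.0, center_y=23.0, radius=3.0)
    (bl, br), (il, ir), (ph_l, ph_r) = cd.simulate_acquisition(
        flow, phantom, geom, cfg, snr_db=20.0, seed=0
    )
    return {
        "bmode": (bl, br), "iq": (il, ir), "phantoms": (ph_l, ph_r),
        "flow": flow, "truth_velocity": 0.34,
    }


@pytest.fixture(scope="session")
def steady_measurement(steady_acquisition, geom, cfg):
    bl, br = steady_acquisition["bmode"]
    il, ir = steady_acquisition["iq"]
    res, arts = cd.run_measurement(bl, br, il, ir, geom, cfg, return_artifacts=True)
    return res, arts


def disk_frame(cx, cy, r, shape=(400, 128), spacing=(0.1, 0.3),
               origin=None, val_in=20, val_bg=200):
    """Noise-free test image: uniform background with one dark disk (mm coords)."""
    if origin is None:
        origin = -(shape[1] - 1) * spacing[1] / 2.0
    ys = np.arange(shape[0]) * spacing[0]
    xs = origin + np.arange(shape[1]) * spacing[1]
    mask = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2 <= r**2
    return np.where(mask, val_in, val_bg).astype(np.uint8), origin
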