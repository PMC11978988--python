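import numpy as np
import pytest

import fringeflow as ff
from fringeflow.reconstruct import NOMINAL_PHASES


@pytest.fixture(scope="session")
def cfg():
    return ff.OpticalConfig()


@pytest.fixture(scope="session")
def psm():
    return ff.PhaseShifterModel()


@pytest.fixture(scope="session")
def sheet():
    return ff.LightSheetProfile()


@pytest.fixture(scope="session")
def cam_small():
    return ff.CameraModel(roi_px=(128, 128))


@pytest.fixture(scope="session")
def bead_triplet(cfg, sheet):
    """Rendered 3-phase triplet of a bright bead field (default noise), 256 px."""
    cam = ff.CameraModel(roi_px=(256, 256))
    phantom = ff.make_bead_phantom(30, (24.0, 24.0, 0.0), 1.5, seed=1)
    rng = np.random.default_rng(42)
    frames = np.stack(
        [ff.render_frame(phantom, cfg, sheet, cam, p, 0.8, rng=rng) for p in NOMINAL_PHASES]
    )
    return frames, cam, phantom


@pytest.fixture(scope="session")
def dye_sweep(cfg, psm, sheet):
    """Calibration voltage sweep of a dye channel (default noise), 64x700 ROI."""
    cam = ff.CameraModel(roi_px=(64, 700), frame_rate_hz=100.0)
    proto = ff.AcquisitionProtocol(mode="calibration_sweep")
    ny, nx = cam.roi_px
    extent = (nx * cfg.pixel_um, ny * cfg.pixel_um, 8.0)
    phantom = ff.make_dye_phantom(extent, 50.0, seed=11)
    stack = ff.run_calibration_sweep(phantom, cfg, sheet, psm, cam, proto, seed=3)
    return stack, cam
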