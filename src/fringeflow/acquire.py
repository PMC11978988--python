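"""Raw-frame rendering and the two acquisition protocols.

A frame is the widefield image of the emitters excited by the patterned
light sheet: per-emitter expected signal = brightness x sheet weight
(Gaussian in the distance between emitter and sheet plane along the flow
axis, with thickness FWHM evaluated at the emitter's x) x illumination
pattern at the emitter's x; emitters are binned to the nearest pixel and
convolved with the detection PSF; camera noise is Poisson shot noise plus
Gaussian read noise, converted to ADU.

The two crossed sheets are modelled as a single effective sheet carrying
the interference pattern: their overlap defines the image plane.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    AcquisitionProtocol,
    CameraModel,
    FlowTrajectory,
    LightSheetProfile,
    OpticalConfig,
    PhaseShifterModel,
)
from .optics import detection_psf_otf, phase_from_voltage, pattern_intensity, sheet_fwhm_at
from .phantoms import Phantom
from .stackio import META_COLUMNS, FrameStack

__all__ = [
    "expected_frame",
    "render_frame",
    "run_calibration_sweep",
    "run_flow_scan",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def expected_frame(
    phantom: Phantom,
    cfg: OpticalConfig,
    ls: LightSheetProfile,
    cam: CameraModel,
    phase_rad: float,
    modulation_depth: float = 0.8,
    sheet_z_um: float = 0.0,
    flow_offset_um: float = 0.0,
    otf: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free expected photon image (before QE and camera conversion).

    ``flow_offset_um`` translates the phantom along the flow axis z (the
    sheet stays at ``sheet_z_um`` in lab coordinates).
    """
    ny, nx = cam.roi_px
    pix = cfg.pixel_um
    img = np.zeros((ny, nx), dtype=float)
    if phantom.n_emitters:
        x, y, z, b = phantom.emitters.T
        z_lab = z + flow_offset_um
        fwhm = np.asarray(sheet_fwhm_at(ls, cfg, x))
        sigma = fwhm * _FWHM_TO_SIGMA
        sheet_w = np.exp(-0.5 * ((z_lab - sheet_z_um) / sigma) ** 2)
        illum = pattern_intensity(cfg, x, phase_rad, modulation_depth)
        signal = b * sheet_w * illum
        col = np.rint(x / pix).astype(int) + nx // 2
        row = np.rint(y / pix).astype(int) + ny // 2
        keep = (col >= 0) & (col < nx) & (row >= 0) & (row < ny) & (signal > 0)
        np.add.at(img, (row[keep], col[keep]), signal[keep])
    if otf is None:
        _, otf = detection_psf_otf(cfg, (ny, nx))
    img = np.fft.ifft2(np.fft.fft2(img) * otf).real
    return np.clip(img, 0.0, None)


def render_frame(
    phantom: Phantom,
    cfg: OpticalConfig,
    ls: LightSheetProfile,
    cam: CameraModel,
    phase_rad: float,
    modulation_depth: float = 0.8,
    sheet_z_um: float = 0.0,
    flow_offset_um: float = 0.0,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
    otf: np.ndarray | None = None,
) -> np.ndarray:
    """One camera frame in ADU; reproducible for a given rng/seed."""
    photons = expected_frame(
        phantom, cfg, ls, cam, phase_rad, modulation_depth, sheet_z_um, flow_offset_um, otf
    )
    electrons = cam.qe * photons
    if noise:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        electrons = rng.poisson(electrons).astype(float)
        electrons += rng.normal(0.0, cam.read_noise_e, size=electrons.shape)
    return (electrons / cam.gain_e_per_adu + cam.offset_adu).astype(np.float32)


def _empty_meta() -> pd.DataFrame:
    return pd.DataFrame(columns=META_COLUMNS)


def run_calibration_sweep(
    phantom: Phantom,
    cfg: OpticalConfig,
    ls: LightSheetProfile,
    psm: PhaseShifterModel,
    cam: CameraModel,
    protocol: AcquisitionProtocol,
    seed: int | np.random.Generator = 0,
    modulation_depth: float = 0.8,
    noise: bool = True,
) -> FrameStack:
    """Static voltage-sweep acquisition of a dye-filled channel.

    One frame per sweep voltage per repetition, ordered repetition-major;
    the commanded phase follows the quadratic shifter law, with optional
    multiplicative power jitter if the shifter model requests it.
    """
    if protocol.mode != "calibration_sweep":
        raise ValueError("protocol mode must be 'calibration_sweep'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, otf = detection_psf_otf(cfg, cam.roi_px)
    frames, rows = [], []
    dt = 1.0 / cam.frame_rate_hz
    i = 0
    for _rep in range(protocol.sweep_repetitions):
        for v in protocol.sweep_voltages_v:
            phi = phase_from_voltage(psm, v)
            if psm.power_jitter_frac > 0:
                phi *= 1.0 + rng.normal(0.0, psm.power_jitter_frac)
            frames.append(
                render_frame(
                    phantom, cfg, ls, cam, phi, modulation_depth,
                    rng=rng, noise=noise, otf=otf,
                )
            )
            rows.append((i, i * dt, v, np.nan, phi, 0.0))
            i += 1
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return FrameStack(np.stack(frames), meta)


def run_flow_scan(
    phantom: Phantom,
    trajectory: FlowTrajectory,
    cfg: OpticalConfig,
    ls: LightSheetProfile,
    psm: PhaseShifterModel,
    cam: CameraModel,
    protocol: AcquisitionProtocol,
    seed: int | np.random.Generator = 0,
    modulation_depth: float = 0.8,
    noise: bool = True,
) -> FrameStack:
    """Three-phase flow-scan acquisition.

    Frames are taken at 1/frame_rate intervals while the phantom advances
    along z; the commanded phase cycles through the protocol's three drive
    voltages (nominally 0, 2pi/3, 4pi/3). Each complete (0, 1, 2) triplet is
    one z-plane whose nominal position is the mean flow position of its
    frames.
    """
    if protocol.mode != "flow_scan":
        raise ValueError("protocol mode must be 'flow_scan'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / cam.frame_rate_hz
    span = trajectory.end_z_um - trajectory.start_z_um
    if trajectory.speed_um_s > 0:
        n_frames = int(math.floor(span / (trajectory.speed_um_s * dt))) + 1
    else:
        n_frames = 3
    if n_frames < 3:
        raise ValueError("trajectory shorter than one 3-phase triplet")
    phases = [phase_from_voltage(psm, v) for v in protocol.phase_cycle_voltages_v]
    _, otf = detection_psf_otf(cfg, cam.roi_px)
    frames, rows = [], []
    for i in range(n_frames):
        t = i * dt
        z_flow = trajectory.position(t)
        if trajectory.jitter_sd_um > 0:
            z_flow += rng.normal(0.0, trajectory.jitter_sd_um)
        idx = i % 3
        phi = phases[idx]
        if psm.power_jitter_frac > 0:
            phi *= 1.0 + rng.normal(0.0, psm.power_jitter_frac)
        frames.append(
            render_frame(
                phantom, cfg, ls, cam, phi, modulation_depth,
                flow_offset_um=z_flow, rng=rng, noise=noise, otf=otf,
            )
        )
        rows.append((i, t, protocol.phase_cycle_voltages_v[idx], idx, phi, z_flow))
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return FrameStack(np.stack(frames), meta)
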