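"""Closed-form optical forward model of the chip.

Covers the two-beam interference pattern, the thermal phase shifter
(voltage to phase), the Gaussian-limit light-sheet thickness profile, the
widefield detection PSF/OTF, the theoretical one-dimensional SIM resolution
gain and a sampling sanity check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import LightSheetProfile, OpticalConfig, PhaseShifterModel

__all__ = [
    "pattern_period",
    "carrier_frequency",
    "pattern_intensity",
    "phase_from_voltage",
    "voltage_for_phase",
    "sheet_fwhm_at",
    "detection_psf_otf",
    "theoretical_sim_gain",
    "validate_sampling",
    "SamplingReport",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def pattern_period(cfg: OpticalConfig) -> float:
    """Theoretical fringe period of the two-beam interference pattern, nm.

    p = lambda_exc / (2 n sin(theta)) with n the index of the fused-silica
    chip in which the semi-angle theta between the beams is defined; the
    transverse spatial frequency is unchanged across the flat silica/water
    interface.
    """
    theta = math.radians(cfg.semi_angle_deg)
    s = math.sin(theta)
    if s == 0.0:
        raise ValueError("degenerate interference geometry (semi-angle 0)")
    return cfg.lambda_exc_nm / (2.0 * cfg.n_chip * s)


def carrier_frequency(cfg: OpticalConfig) -> float:
    """Carrier spatial frequency k0 = 1/p in cycles/um, using the effective period."""
    return 1000.0 / cfg.carrier_period_effective_nm()


def pattern_intensity(
    cfg: OpticalConfig,
    x_um: np.ndarray | float,
    phi_rad: float,
    modulation_depth: float = 0.8,
) -> np.ndarray:
    """Normalized illumination intensity I(x) = 1 + m cos(2 pi x / p + phi).

    ``x_um`` is the lateral coordinate along the modulation axis; the period
    is the config's effective carrier period (791 nm by default).
    """
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must lie in [0, 1]")
    p_um = cfg.carrier_period_effective_nm() * 1e-3
    x = np.asarray(x_um, dtype=float)
    return 1.0 + modulation_depth * np.cos(2.0 * np.pi * x / p_um + phi_rad)


def phase_from_voltage(psm: PhaseShifterModel, v: float | np.ndarray) -> float | np.ndarray:
    """Optical phase (rad) at drive voltage ``v``: quadratic in V (linear in power)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("drive voltage must be non-negative")
    phi = psm.phi_offset_rad + psm.phi_ref_rad * (v / psm.v_ref_v) ** 2
    return float(phi) if phi.ndim == 0 else phi


def voltage_for_phase(psm: PhaseShifterModel, phi_rad: float) -> float:
    """Drive voltage producing phase ``phi_rad``; exact inverse of phase_from_voltage."""
    if phi_rad < psm.phi_offset_rad:
        raise ValueError("unreachable phase (below the 0 V offset)")
    return psm.v_ref_v * math.sqrt((phi_rad - psm.phi_offset_rad) / psm.phi_ref_rad)


def sheet_fwhm_at(
    ls: LightSheetProfile, cfg: OpticalConfig, z_um: float | np.ndarray
) -> float | np.ndarray:
    """Light-sheet thickness FWHM (um) at position ``z_um`` along propagation.

    Gaussian-beam divergence: w0 = FWHM_focus / sqrt(2 ln 2), Rayleigh range
    zR = pi w0^2 n_medium / lambda_exc, FWHM(z) = FWHM_focus sqrt(1 + ((z -
    z_center)/zR)^2).
    """
    w0 = ls.fwhm_focus_um / math.sqrt(2.0 * math.log(2.0))
    z_r = math.pi * w0**2 * cfg.n_medium / (cfg.lambda_exc_nm * 1e-3)
    z = np.asarray(z_um, dtype=float)
    fwhm = ls.fwhm_focus_um * np.sqrt(1.0 + ((z - ls.z_center_um) / z_r) ** 2)
    return float(fwhm) if fwhm.ndim == 0 else fwhm


def sheet_rayleigh_range(ls: LightSheetProfile, cfg: OpticalConfig) -> float:
    """Rayleigh range (um) of the Gaussian-limit sheet."""
    w0 = ls.fwhm_focus_um / math.sqrt(2.0 * math.log(2.0))
    return math.pi * w0**2 * cfg.n_medium / (cfg.lambda_exc_nm * 1e-3)


def detection_psf_otf(
    cfg: OpticalConfig, shape: tuple[int, int], pixel_um: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Widefield detection PSF and OTF sampled on a ``shape`` pixel grid.

    The incoherent OTF is the autocorrelation of a circular pupil — the
    radially symmetric "chat" function with cutoff kc = 2 NA / lambda_em —
    evaluated analytically on the FFT frequency grid (frequency origin at
    bin 0, ``np.fft`` layout). The PSF is its inverse transform, normalized
    to unit sum. OTF(0) = 1.

    Returns ``(psf, otf)``; the PSF is centred (origin at the array centre)
    for direct visual use, the OTF is in FFT layout for direct use in
    frequency-domain filtering.
    """
    if pixel_um is None:
        pixel_um = cfg.pixel_um
    rec = pixel_um > cfg.lambda_em_nm * 1e-3 / (4.0 * cfg.na_det)
    if rec:
        warnings.warn(
            "grid pixel exceeds lambda_em/(4 NA); PSF may be undersampled",
            stacklevel=2,
        )
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_um)
    fx = np.fft.fftfreq(nx, d=pixel_um)
    kr = np.hypot(fy[:, None], fx[None, :])
    rho = np.minimum(kr / cfg.cutoff_um, 1.0)
    otf = (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho**2))
    otf[kr >= cfg.cutoff_um] = 0.0
    psf = np.fft.ifft2(otf).real
    psf = np.fft.fftshift(psf)
    psf = np.clip(psf, 0.0, None)
    psf /= psf.sum()
    return psf, otf


def theoretical_sim_gain(cfg: OpticalConfig, period_nm: float | None = None) -> float:
    """Theoretical 1D resolution improvement (kc + k0) / kc, capped at 2.

    ``period_nm`` defaults to the config's effective carrier period.
    """
    if period_nm is None:
        period_nm = cfg.carrier_period_effective_nm()
    if period_nm <= 0:
        raise ValueError("pattern period must be positive")
    k0 = 1000.0 / period_nm  # cycles/um
    return min((cfg.cutoff_um + k0) / cfg.cutoff_um, 2.0)


@dataclass
class SamplingReport:
    """Result of :func:`validate_sampling`."""

    pixel_um: float
    cutoff_um: float
    extended_cutoff_um: float
    pixels_per_period: float
    detection_nyquist_ok: bool
    extended_nyquist_ok: bool
    warnings: list[str]


def validate_sampling(cfg: OpticalConfig) -> SamplingReport:
    """Check camera sampling against the detection and extended SIM cutoffs.

    Raw frames must satisfy Nyquist for the detection cutoff kc; the
    reconstruction extends support to kc + k0 and is computed on a 2x
    zero-padded grid, so the extended check reports whether the *raw* pixel
    already satisfies the extended cutoff (it need not when the
    reconstruction grid is upsampled). Fringe sampling below ~2.2 px/period
    also draws a warning.
    """
    pixel = cfg.pixel_um
    kc = cfg.cutoff_um
    p_um = cfg.carrier_period_effective_nm() * 1e-3
    k0 = 1.0 / p_um
    k_ext = kc + k0
    ppp = p_um / pixel
    msgs: list[str] = []
    det_ok = pixel <= 1.0 / (2.0 * kc)
    ext_ok = pixel <= 1.0 / (2.0 * k_ext)
    if not det_ok:
        msgs.append(
            f"detection Nyquist violation: pixel {pixel*1e3:.0f} nm > "
            f"{1e3 / (2 * kc):.0f} nm required for kc={kc:.3f} 1/um"
        )
    if not ext_ok:
        msgs.append(
            "extended-cutoff Nyquist not met on the raw grid; reconstruction "
            "uses a 2x padded grid"
        )
    if ppp <= 2.0 + 1e-9:
        msgs.append("fringe at sampling limit (<= 2 px/period)")
    elif ppp < 2.2:
        msgs.append(f"fringe marginally sampled at {ppp:.2f} px/period")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return SamplingReport(
        pixel_um=pixel,
        cutoff_um=kc,
        extended_cutoff_um=k_ext,
        pixels_per_period=ppp,
        detection_nyquist_ok=det_ok,
        extended_nyquist_ok=ext_ok,
        warnings=msgs,
    )
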