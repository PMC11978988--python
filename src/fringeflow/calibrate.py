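"""Fringe-pattern calibration from a voltage-sweep acquisition.

Reproduces the bench calibration workflow: average the repeated frames per
voltage, take a line profile across the fringes, high-pass it to remove the
light-sheet envelope without touching the carrier, track sub-pixel peak
positions, average the per-step shifts over >20 peaks to get the fringe
period and the cumulative phase per voltage, fit the quadratic
phase-vs-voltage law, and solve for the drive voltages of the 3-phase
scheme (0, 2pi/3, 4pi/3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import OpticalConfig
from .stackio import META_COLUMNS, FrameStack

__all__ = [
    "CalibrationResult",
    "average_repetitions",
    "extract_profile",
    "highpass_profile",
    "detect_peaks",
    "estimate_shift_and_period",
    "fit_phase_vs_voltage",
    "calibrate_sweep",
]

TWO_PI = 2.0 * math.pi


@dataclass
class CalibrationResult:
    """Output of the sweep calibration."""

    period_px: float
    period_nm: float | None
    voltages_v: list[float]
    shifts_px: list[float]  # per-step mean shift between consecutive voltages
    phases_rad: list[float]  # cumulative phase per voltage (0 at the first)
    peaks_used: list[int]
    coeff_rad_per_v2: float
    fit_residual_rms_rad: float
    solved_voltages_v: dict[str, float]
    low_confidence: bool
    monotone: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))

    def table(self) -> pd.DataFrame:
        shifts = [0.0] + list(self.shifts_px)
        return pd.DataFrame(
            {
                "voltage_v": self.voltages_v,
                "shift_px": shifts,
                "phase_rad": self.phases_rad,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.table().to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Phase-vs-voltage plot with the quadratic fit (PNG/PDF by suffix)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        v = np.asarray(self.voltages_v)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.plot(v, self.phases_rad, "o", label="measured")
        vv = np.linspace(0, v.max() * 1.05, 200)
        a = self.coeff_rad_per_v2
        ax.plot(vv, a * (vv**2 - v[0] ** 2), "-", label=f"fit a={a:.4f} rad/V$^2$")
        ax.set_xlabel("drive voltage (V)")
        ax.set_ylabel("cumulative phase (rad)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def average_repetitions(stack: FrameStack) -> FrameStack:
    """Pixel-wise mean across repetitions, grouped by drive voltage.

    Output holds one frame per voltage, ordered by voltage. Unequal
    repetition counts per voltage raise.
    """
    volts = stack.meta["voltage_v"].to_numpy()
    uniq = np.unique(volts)
    counts = {v: int(np.sum(volts == v)) for v in uniq}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal repetition counts per voltage: {counts}")
    frames, rows = [], []
    for i, v in enumerate(uniq):
        sel = volts == v
        frames.append(stack.frames[sel].mean(axis=0))
        phase = float(stack.meta.loc[sel, "phase_rad"].mean())
        rows.append((i, np.nan, v, np.nan, phase, 0.0))
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return FrameStack(np.stack(frames).astype(np.float32), meta)


def extract_profile(frame: np.ndarray, row_band: tuple[int, int]) -> np.ndarray:
    """Column-wise mean over the given row band (a region of uniform sheet)."""
    lo, hi = row_band
    frame = np.asarray(frame)
    if not (0 <= lo < hi <= frame.shape[0]):
        raise ValueError("row band empty or outside the frame")
    return frame[lo:hi].mean(axis=0)


def highpass_profile(
    profile: np.ndarray, period_px: float, cutoff_frac: float = 0.3
) -> np.ndarray:
    """Remove the slow light-sheet envelope, preserving the fringe carrier.

    A raised-cosine spectral mask zeroes frequencies below
    ``cutoff_frac / period_px`` (default 0.3x the expected carrier) with a
    smooth transition reaching unity well below the carrier, so the carrier
    amplitude is preserved within 2%. The output is zero-mean.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    if n < 4 * period_px:
        raise ValueError("profile shorter than 4 fringe periods")
    f = np.fft.rfftfreq(n, d=1.0)
    fc = cutoff_frac / period_px
    hw = 0.5 * fc
    mask = np.ones_like(f)
    mask[f <= fc - hw] = 0.0
    trans = (f > fc - hw) & (f < fc + hw)
    mask[trans] = 0.5 * (1.0 - np.cos(np.pi * (f[trans] - (fc - hw)) / (2.0 * hw)))
    spec = np.fft.rfft(profile)
    return np.fft.irfft(spec * mask, n=n)


def detect_peaks(profile: np.ndarray, prominence_frac: float = 0.1) -> np.ndarray:
    """Sub-pixel fringe-peak positions in a high-passed profile.

    Local maxima above a prominence floor (fraction of the profile maximum),
    each refined by a 3-point parabolic fit. Positions are strictly
    increasing.
    """
    profile = np.asarray(profile, dtype=float)
    prom = prominence_frac * profile.max()
    idx, _ = find_peaks(profile, prominence=prom)
    idx = idx[(idx > 0) & (idx < profile.size - 1)]
    if idx.size < 3:
        raise ValueError("profile too short for calibration (< 3 fringe peaks)")
    ym, y0, yp = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = ym - 2.0 * y0 + yp
    delta = np.where(denom != 0, (ym - yp) / (2.0 * denom), 0.0)
    return idx + delta


def _match_displacements(a: np.ndarray, b: np.ndarray, period_px: float) -> np.ndarray:
    """Signed displacements b - a of nearest-neighbour matched peaks (within p/2)."""
    j = np.searchsorted(b, a)
    cand_lo = np.clip(j - 1, 0, b.size - 1)
    cand_hi = np.clip(j, 0, b.size - 1)
    d_lo = b[cand_lo] - a
    d_hi = b[cand_hi] - a
    d = np.where(np.abs(d_lo) <= np.abs(d_hi), d_lo, d_hi)
    # nearest-neighbour matching aliases at half a period; displacements near
    # that limit are ambiguous, so refuse to track them
    if np.median(np.abs(d)) > 0.45 * period_px:
        raise ValueError("phase step too large to track (median shift ~ period/2)")
    return d[np.abs(d) <= period_px / 2.0]


def estimate_shift_and_period(
    peaks_by_voltage: list[np.ndarray],
    voltages_v: list[float] | None = None,
    min_peaks: int = 21,
) -> dict:
    """Fringe period and per-step shifts from matched peak tracks.

    Period = mean inter-peak spacing pooled over all voltage steps. Shift
    between consecutive voltages = mean displacement of nearest-neighbour
    matched peaks (within half a period). Cumulative phase(V) = 2pi x
    cumulative shift / period, sign-fixed so phase increases with voltage
    for a monotone shifter.
    """
    if len(peaks_by_voltage) < 2:
        raise ValueError("need at least 2 voltage steps")
    spacings = np.concatenate([np.diff(p) for p in peaks_by_voltage])
    period = float(spacings.mean())
    shifts, used = [], [len(peaks_by_voltage[0])]
    for a, b in zip(peaks_by_voltage, peaks_by_voltage[1:]):
        d = _match_displacements(np.asarray(a), np.asarray(b), period)
        shifts.append(float(d.mean()))
        used.append(int(d.size))
    cum = np.concatenate([[0.0], np.cumsum(shifts)])
    sign = -1.0 if cum[-1] < 0 else 1.0
    phases = sign * TWO_PI * cum / period
    low_conf = any(u < min_peaks for u in used)
    monotone = bool(np.all(np.diff(phases) >= -1e-9))
    return {
        "period_px": period,
        "shifts_px": [sign * s for s in shifts],
        "phases_rad": phases.tolist(),
        "peaks_used": used,
        "low_confidence": low_conf,
        "monotone": monotone,
        "voltages_v": list(voltages_v) if voltages_v is not None else None,
    }


def fit_phase_vs_voltage(
    phases_rad: np.ndarray,
    voltages_v: np.ndarray,
    v_anchor: float | None = None,
) -> dict:
    """Least-squares fit of the power law phase = a (V^2 - V_anchor^2).

    The measured cumulative phase is zero at the first swept voltage, while
    the shifter law is anchored at 0 V <-> 0 rad, so the model subtracts the
    anchor term; with data starting at 0 V this reduces to phase = a V^2.
    Returns the coefficient, the RMS residual and the drive voltages solving
    phase in {0, 2pi/3, 4pi/3}, reported to 0.01 V.
    """
    phases = np.asarray(phases_rad, dtype=float)
    volts = np.asarray(voltages_v, dtype=float)
    if phases.size < 3:
        raise ValueError("need at least 3 (voltage, phase) points")
    if v_anchor is None:
        v_anchor = float(volts[0])
    x = volts**2 - v_anchor**2
    a = float(np.dot(x, phases) / np.dot(x, x))
    resid = phases - a * x
    monotone = bool(np.all(np.diff(phases) >= -1e-9))
    solved = {
        "0": 0.0,
        "2pi/3": round(math.sqrt((TWO_PI / 3.0) / a), 2),
        "4pi/3": round(math.sqrt((2.0 * TWO_PI / 3.0) / a), 2),
    }
    return {
        "coeff_rad_per_v2": a,
        "fit_residual_rms_rad": float(np.sqrt(np.mean(resid**2))),
        "solved_voltages_v": solved,
        "monotone": monotone,
    }


def calibrate_sweep(
    stack: FrameStack,
    cfg: OpticalConfig | None = None,
    row_band: tuple[int, int] | None = None,
    expected_period_px: float | None = None,
    cutoff_frac: float = 0.3,
) -> CalibrationResult:
    """End-to-end calibration of a voltage-sweep FrameStack."""
    if expected_period_px is None:
        if cfg is None:
            raise ValueError("need cfg or expected_period_px")
        expected_period_px = cfg.carrier_period_effective_nm() * 1e-3 / cfg.pixel_um
    avg = average_repetitions(stack)
    ny = avg.shape[0]
    if row_band is None:
        row_band = (max(0, ny // 2 - max(ny // 8, 1)), min(ny, ny // 2 + max(ny // 8, 1)))
    peaks = []
    for frame in avg.frames:
        prof = extract_profile(frame, row_band)
        hp = highpass_profile(prof, expected_period_px, cutoff_frac)
        peaks.append(detect_peaks(hp))
    volts = avg.meta["voltage_v"].to_list()
    core = estimate_shift_and_period(peaks, volts)
    fit = fit_phase_vs_voltage(np.array(core["phases_rad"]), np.array(volts))
    period_nm = None
    if cfg is not None:
        period_nm = core["period_px"] * cfg.pixel_um * 1000.0
    return CalibrationResult(
        period_px=core["period_px"],
        period_nm=period_nm,
        voltages_v=volts,
        shifts_px=core["shifts_px"],
        phases_rad=core["phases_rad"],
        peaks_used=core["peaks_used"],
        coeff_rad_per_v2=fit["coeff_rad_per_v2"],
        fit_residual_rms_rad=fit["fit_residual_rms_rad"],
        solved_voltages_v=fit["solved_voltages_v"],
        low_confidence=core["low_confidence"],
        monotone=core["monotone"] and fit["monotone"],
    )
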