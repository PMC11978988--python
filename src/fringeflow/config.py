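"""Configuration objects for the integrated structured light-sheet flow cytometer.

All quantities carry their unit in the field name (``lambda_exc_nm``,
``cam_pixel_um`` ...). Internal computation is done in micrometres and
nanometres; conversion happens only at these boundaries.

Coordinate convention used throughout the package:

* ``x`` — modulation axis: the interference fringes run across it, and it is
  also the light-sheet propagation axis (sheet thickness varies with x).
* ``z`` — flow/scan axis: cells advance along it; the sheet sections it.
* ``y`` — detection optical axis's in-plane partner on camera frames; frames
  are indexed ``(row, col) = (y, x)``, volumes ``(plane=z, y, x)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "OpticalConfig",
    "PhaseShifterModel",
    "LightSheetProfile",
    "CameraModel",
    "FlowTrajectory",
    "AcquisitionProtocol",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


@dataclass
class OpticalConfig:
    """Optical parameters of chip, illumination and detection path.

    Defaults describe the reference device: 561 nm excitation interfering at
    a 15 degree semi-angle inside the fused-silica chip, detected through a
    40x / 1.15 NA water-immersion objective with a 1.5x tube lens onto a
    6.5 um camera pixel.

    ``carrier_period_nm`` is the fringe period actually used by the
    simulator and as the nominal carrier in reconstruction. It defaults to
    the measured 791 nm; set it to ``None`` to fall back to the closed-form
    theoretical period (see :func:`fringeflow.optics.pattern_period`).
    """

    lambda_exc_nm: float = 561.0
    lambda_em_nm: float = 600.0
    n_medium: float = 1.333
    n_chip: float = 1.458
    semi_angle_deg: float = 15.0
    na_det: float = 1.15
    mag_total: float = 60.0
    cam_pixel_um: float = 6.5
    carrier_period_nm: float | None = 791.0

    def __post_init__(self) -> None:
        if not 0.0 < self.semi_angle_deg < 90.0:
            raise ValueError("semi_angle_deg must lie in (0, 90)")
        if self.lambda_exc_nm <= 0 or self.lambda_em_nm <= 0:
            raise ValueError("wavelengths must be positive")
        if not 0.0 < self.na_det < 1.52:
            raise ValueError("na_det must lie in (0, 1.52)")
        if self.mag_total <= 0 or self.cam_pixel_um <= 0:
            raise ValueError("magnification and camera pixel must be positive")

    @property
    def pixel_um(self) -> float:
        """Object-side pixel pitch, um (camera pixel / total magnification)."""
        return self.cam_pixel_um / self.mag_total

    @property
    def cutoff_um(self) -> float:
        """Incoherent detection cutoff kc = 2 NA / lambda_em, cycles/um."""
        return 2.0 * self.na_det / (self.lambda_em_nm * 1e-3)

    def carrier_period_effective_nm(self) -> float:
        """Fringe period used downstream: override if set, else theoretical."""
        if self.carrier_period_nm is not None:
            return float(self.carrier_period_nm)
        from .optics import pattern_period

        return pattern_period(self)


@dataclass
class PhaseShifterModel:
    """Thermal phase shifter: optical phase proportional to dissipated power.

    For a resistive microheater at constant resistance the dissipated power
    is proportional to V^2, hence ``phase(V) = phi_offset + phi_ref *
    (V / v_ref)**2``. Defaults anchor 4pi/3 rad at 5.86 V with zero phase at
    0 V. ``drift_ppk`` records the measured 0.18% peak-to-peak electrical
    stability of the heater; it is informational and not simulated unless
    ``power_jitter_frac`` is set, which adds a multiplicative jitter on the
    dissipated power per rendered frame.
    """

    v_ref_v: float = 5.86
    phi_ref_rad: float = 4.0 * math.pi / 3.0
    phi_offset_rad: float = 0.0
    drift_ppk: float = 0.0018
    power_jitter_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.v_ref_v <= 0:
            raise ValueError("v_ref_v must be positive (configuration error)")
        if self.phi_ref_rad < 0:
            raise ValueError("phi_ref_rad must be non-negative")


@dataclass
class LightSheetProfile:
    """Gaussian-limit light-sheet thickness profile along its propagation axis.

    Anchored at the focal waist (``fwhm_focus_um``, default 1.1 um at the
    channel centre); away from focus the thickness follows the Gaussian-beam
    divergence law with the Rayleigh range set by the waist, the excitation
    wavelength and the medium index.
    """

    fwhm_focus_um: float = 1.1
    z_center_um: float = 0.0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_focus_um <= 0:
            raise ValueError("fwhm_focus_um must be positive")
        if self.model != "gaussian":
            raise ValueError("only the 'gaussian' sheet model is available")


@dataclass
class CameraModel:
    """sCMOS-like camera: QE, Poisson shot noise, Gaussian read noise, ADU conversion."""

    qe: float = 0.8
    read_noise_e: float = 1.6
    offset_adu: float = 100.0
    gain_e_per_adu: float = 0.46
    frame_rate_hz: float = 50.0
    roi_px: tuple[int, int] = (512, 700)

    def __post_init__(self) -> None:
        if min(self.qe, self.read_noise_e + 1e-12, self.gain_e_per_adu) <= 0:
            raise ValueError("camera parameters must be positive")
        if not 0 < self.frame_rate_hz <= 400.0:
            raise ValueError("frame_rate_hz must lie in (0, 400]")
        self.roi_px = (int(self.roi_px[0]), int(self.roi_px[1]))
        if min(self.roi_px) <= 0:
            raise ValueError("roi_px must be positive")


@dataclass
class FlowTrajectory:
    """Constant-speed flow along z with optional per-frame positional jitter."""

    speed_um_s: float = 10.0
    start_z_um: float = -10.0
    end_z_um: float = 10.0
    jitter_sd_um: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_um_s < 0:
            raise ValueError("speed_um_s must be non-negative")
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be non-negative")

    def position(self, t_s: float) -> float:
        return self.start_z_um + self.speed_um_s * t_s


def _default_sweep() -> list[float]:
    # 2.0 -> 7.5 V in 0.5 V increments (12 values).
    return [2.0 + 0.5 * i for i in range(12)]


def _default_cycle() -> list[float]:
    return [0.0, 4.15, 5.86]


@dataclass
class AcquisitionProtocol:
    """Acquisition protocol: static voltage-sweep calibration or 3-phase flow scan."""

    mode: str = "flow_scan"
    sweep_voltages_v: list[float] = field(default_factory=_default_sweep)
    sweep_repetitions: int = 8
    phase_cycle_voltages_v: list[float] = field(default_factory=_default_cycle)

    def __post_init__(self) -> None:
        if self.mode not in ("calibration_sweep", "flow_scan"):
            raise ValueError("mode must be 'calibration_sweep' or 'flow_scan'")
        v = list(self.sweep_voltages_v)
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sweep voltages must be strictly increasing")
        if self.sweep_repetitions < 1:
            raise ValueError("sweep_repetitions must be >= 1")
        if len(self.phase_cycle_voltages_v) != 3:
            raise ValueError("phase cycle must list exactly 3 voltages")


_BLOCKS: dict[str, type] = {
    "optics": OpticalConfig,
    "phase_shifter": PhaseShifterModel,
    "light_sheet": LightSheetProfile,
    "camera": CameraModel,
    "flow": FlowTrajectory,
    "protocol": AcquisitionProtocol,
}


@dataclass
class ExperimentConfig:
    """Bundle of all configuration blocks plus global seed and output directory."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    phase_shifter: PhaseShifterModel = field(default_factory=PhaseShifterModel)
    light_sheet: LightSheetProfile = field(default_factory=LightSheetProfile)
    camera: CameraModel = field(default_factory=CameraModel)
    flow: FlowTrajectory = field(default_factory=FlowTrajectory)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    phantom: dict[str, Any] = field(default_factory=dict)
    reconstruction: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["camera"]["roi_px"] = list(d["camera"]["roi_px"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for name, block_cls in _BLOCKS.items():
            if name in data:
                block = data.pop(name)
                if not isinstance(block, dict):
                    raise ValueError(f"config block {name!r} must be a mapping")
                known = {f.name for f in fields(block_cls)}
                unknown = set(block) - known
                if unknown:
                    raise ValueError(
                        f"unknown keys in config block {name!r}: {sorted(unknown)}"
                    )
                kwargs[name] = block_cls(**block)
        for name in ("phantom", "reconstruction", "seed", "out_dir"):
            if name in data:
                kwargs[name] = data.pop(name)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return ExperimentConfig.from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a resolved (defaults filled) config as YAML or JSON."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
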