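"""Seeded end-to-end scenario runner: simulation -> calibration ->
reconstruction -> volume, as reproducible experiments.

All randomness flows from one global seed through named per-stage
substreams (the stage name is hashed into the spawn key), so any stage can
be re-run independently with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import acquire, calibrate, phantoms, reconstruct, volume
from .config import ExperimentConfig, FlowTrajectory, save_config

__all__ = ["stage_rng", "run_scenario", "ScenarioOutput"]

log = logging.getLogger("fringeflow")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big") % 2**31
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(h,)))


@dataclass
class ScenarioOutput:
    """What a scenario produced, with the resolved config and seed."""

    name: str
    seed: int
    results: dict[str, Any]
    artifacts: dict[str, Any]

    def report(self) -> dict[str, Any]:
        return {"scenario": self.name, "seed": self.seed, **self.results}


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return out


def run_scenario(
    name: str,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> ScenarioOutput:
    """Run one of the canned experiments.

    ``calibration``: dye-filled channel -> voltage sweep -> fringe period,
    phase-vs-voltage fit and solved 3-phase drive voltages.

    ``flow_cell``: membrane-labelled cell phantom -> 3-phase flow scan ->
    per-plane SIM reconstruction -> restacked volume with throughput figures.

    ``bead_resolution``: sub-diffraction bead field -> one 3-phase triplet ->
    reconstruction and resolution-gain report.

    Outputs are pure functions of (config, seed); if ``out_dir`` is given,
    the resolved config and a JSON report are written alongside the arrays.
    """
    cfg = config if config is not None else ExperimentConfig()
    if seed is None:
        seed = cfg.seed
    if name == "calibration":
        out = _scenario_calibration(cfg, seed)
    elif name == "flow_cell":
        out = _scenario_flow_cell(cfg, seed)
    elif name == "bead_resolution":
        out = _scenario_bead_resolution(cfg, seed)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out_dir / "config_resolved.yaml")
        (out_dir / "report.json").write_text(json.dumps(out.report(), indent=2, default=float))
    return out


def _scenario_calibration(cfg: ExperimentConfig, seed: int) -> ScenarioOutput:
    from dataclasses import replace

    protocol = replace(cfg.protocol, mode="calibration_sweep")
    cam = replace(cfg.camera, frame_rate_hz=100.0)
    p = cfg.phantom
    ny, nx = cam.roi_px
    extent = (
        nx * cfg.optics.pixel_um,
        ny * cfg.optics.pixel_um,
        p.get("dye_depth_um", 6.0),
    )
    phantom = _timed(
        "phantom",
        phantoms.make_dye_phantom,
        extent,
        p.get("dye_density_per_um3", 50.0),
        seed=int(stage_rng(seed, "phantom").integers(2**31)),
    )
    stack = _timed(
        "acquire",
        acquire.run_calibration_sweep,
        phantom,
        cfg.optics,
        cfg.light_sheet,
        cfg.phase_shifter,
        cam,
        protocol,
        seed=stage_rng(seed, "acquire"),
        modulation_depth=p.get("modulation_depth", 0.8),
    )
    result = _timed("calibrate", calibrate.calibrate_sweep, stack, cfg.optics)
    return ScenarioOutput(
        "calibration",
        seed,
        results={
            "period_px": result.period_px,
            "period_nm": result.period_nm,
            "coeff_rad_per_v2": result.coeff_rad_per_v2,
            "solved_voltages_v": result.solved_voltages_v,
            "low_confidence": result.low_confidence,
        },
        artifacts={"stack": stack, "calibration": result},
    )


def _scenario_flow_cell(cfg: ExperimentConfig, seed: int) -> ScenarioOutput:
    from dataclasses import replace

    p = cfg.phantom
    radius = p.get("cell_radius_um", 7.5)
    cam = replace(cfg.camera, roi_px=tuple(p.get("roi_px", cfg.camera.roi_px)))
    phantom = _timed(
        "phantom",
        phantoms.make_cell_phantom,
        radius_um=radius,
        shell_thickness_um=p.get("shell_thickness_um", 0.4),
        n_shell=p.get("n_shell", 6000),
        n_vesicles=p.get("n_vesicles", 12),
        seed=int(stage_rng(seed, "phantom").integers(2**31)),
    )
    margin = p.get("flow_margin_um", 2.0)
    traj = FlowTrajectory(
        speed_um_s=cfg.flow.speed_um_s,
        start_z_um=-(radius + margin),
        end_z_um=radius + margin,
        jitter_sd_um=cfg.flow.jitter_sd_um,
    )
    stack = _timed(
        "acquire",
        acquire.run_flow_scan,
        phantom,
        traj,
        cfg.optics,
        cfg.light_sheet,
        cfg.phase_shifter,
        cam,
        cfg.protocol,
        seed=stage_rng(seed, "acquire"),
        modulation_depth=p.get("modulation_depth", 0.8),
    )
    triplets, dropped = volume.group_triplets(stack)
    rp = cfg.reconstruction

    # Planes are reconstructed with the calibrated carrier and commanded
    # phases; per-plane carrier estimation would fail on edge planes where
    # the cell barely intersects the sheet.
    k0_nom = (1000.0 / cfg.optics.carrier_period_effective_nm(), 0.0)

    def recon_fn(frames3: np.ndarray, phases) -> np.ndarray:
        rec = reconstruct.reconstruct_triplet(
            frames3,
            cfg.optics,
            commanded_phases=tuple(phases),
            wiener_w=rp.get("wiener_w", 0.05),
            offset_adu=cam.offset_adu,
            k0_um=None if rp.get("estimate_carrier", False) else k0_nom,
            modulation_depth=p.get("modulation_depth", 0.8),
        )
        return rec.recon

    vol = _timed(
        "assemble",
        volume.assemble_volume,
        triplets,
        recon_fn,
        cfg.flow.speed_um_s,
        cfg.camera.frame_rate_hz,
        cfg.optics.pixel_um / 2.0,  # recon grid is 2x padded
        n_dropped=dropped,
    )
    tp = volume.throughput(
        cfg.flow.speed_um_s,
        cfg.camera.frame_rate_hz,
        cell_extent_um=2.0 * radius,
        gap_um=p.get("intercell_gap_um", 0.0),
    )
    vol.throughput_cells_per_min = tp["cells_per_min"]
    return ScenarioOutput(
        "flow_cell",
        seed,
        results={
            "n_planes": vol.n_planes,
            "z_spacing_um": vol.z_spacing_um,
            "dropped_frames": vol.dropped_frames,
            "throughput": tp,
        },
        artifacts={"stack": stack, "volume": vol},
    )


def _scenario_bead_resolution(cfg: ExperimentConfig, seed: int) -> ScenarioOutput:
    from dataclasses import replace

    p = cfg.phantom
    rp = cfg.reconstruction
    cam = replace(cfg.camera, roi_px=tuple(p.get("roi_px", (256, 256))))
    ny, nx = cam.roi_px
    fov = min(ny, nx) * cfg.optics.pixel_um
    phantom = _timed(
        "phantom",
        phantoms.make_bead_phantom,
        p.get("n_beads", 30),
        (0.9 * fov, 0.9 * fov, 0.0),
        p.get("min_sep_um", 1.5),
        seed=int(stage_rng(seed, "phantom").integers(2**31)),
        brightness=p.get("bead_brightness", 20000.0),
    )
    phases = reconstruct.NOMINAL_PHASES
    rng = stage_rng(seed, "acquire")
    frames = np.stack(
        [
            acquire.render_frame(
                phantom,
                cfg.optics,
                cfg.light_sheet,
                cam,
                phi,
                modulation_depth=p.get("modulation_depth", 0.8),
                rng=rng,
            )
            for phi in phases
        ]
    )
    rec = _timed(
        "reconstruct",
        reconstruct.reconstruct_triplet,
        frames,
        cfg.optics,
        commanded_phases=phases,
        wiener_w=rp.get("wiener_w", 0.05),
        offset_adu=cam.offset_adu,
    )
    gain = reconstruct.measure_gain(
        rec.recon,
        rec.widefield,
        rec.pixel_recon_um,
        rec.pixel_um,
        method=rp.get("gain_method", "fourier_cutoff"),
        cfg=cfg.optics,
    )
    rec.gain_measured = gain
    return ScenarioOutput(
        "bead_resolution",
        seed,
        results={
            "gain_measured": gain,
            "k0_um": rec.k0_um,
            "m_est": rec.m_est,
            "phases_est_rad": rec.phases_est_rad,
        },
        artifacts={"frames": frames, "reconstruction": rec},
    )
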