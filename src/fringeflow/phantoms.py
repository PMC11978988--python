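"""Synthetic emitter-based phantoms: uniform dye, bead fields, membrane-labelled cells.

Each phantom is a set of point emitters (position in um, brightness in
expected photons/frame at the sheet focus). Scaling by sheet intensity,
defocus and the illumination pattern happens in :mod:`fringeflow.acquire`.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Phantom",
    "make_dye_phantom",
    "make_cell_phantom",
    "make_bead_phantom",
]


@dataclass
class Phantom:
    """Point-emitter phantom.

    ``emitters`` is an (N, 4) float array with columns (x_um, y_um, z_um,
    brightness). ``extent_um`` is the (x, y, z) bounding half-open box,
    centred on the origin.
    """

    emitters: np.ndarray
    kind: str
    extent_um: tuple[float, float, float]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emitters = np.atleast_2d(np.asarray(self.emitters, dtype=float))
        if self.emitters.size and self.emitters.shape[1] != 4:
            raise ValueError("emitters must have columns (x, y, z, brightness)")
        if self.emitters.size and np.any(self.emitters[:, 3] <= 0):
            raise ValueError("emitter brightness must be positive")

    @property
    def n_emitters(self) -> int:
        return 0 if self.emitters.size == 0 else self.emitters.shape[0]

    def shifted(self, dz_um: float) -> "Phantom":
        """Copy of the phantom translated along the flow axis z."""
        em = self.emitters.copy()
        em[:, 2] += dz_um
        return Phantom(em, self.kind, self.extent_um, self.seed, dict(self.params))

    def to_csv(self, path: str | Path) -> None:
        """Write emitters as CSV with a JSON sidecar of parameters + seed."""
        path = Path(path)
        df = pd.DataFrame(self.emitters, columns=["x_um", "y_um", "z_um", "brightness"])
        df.to_csv(path, index=False)
        sidecar = {
            "kind": self.kind,
            "extent_um": list(self.extent_um),
            "seed": self.seed,
            "params": self.params,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Phantom":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            df[["x_um", "y_um", "z_um", "brightness"]].to_numpy(),
            meta["kind"],
            tuple(meta["extent_um"]),
            meta["seed"],
            meta.get("params", {}),
        )


def make_dye_phantom(
    extent_um: tuple[float, float, float],
    density_per_um3: float,
    seed: int,
    brightness: float = 50.0,
) -> Phantom:
    """Homogeneous dye solution: Poisson point process of equal-brightness emitters.

    Emulates a fluorescent dye (e.g. rhodamine) filling the channel for
    calibration imaging; expected count = density x volume.
    """
    ex, ey, ez = (float(v) for v in extent_um)
    volume = ex * ey * ez
    if volume <= 0:
        raise ValueError("dye phantom requires a positive-volume extent")
    if density_per_um3 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density_per_um3 * volume))
    pos = (rng.random((n, 3)) - 0.5) * np.array([ex, ey, ez])
    em = np.column_stack([pos, np.full(n, brightness)])
    return Phantom(
        em,
        "dye",
        (ex, ey, ez),
        seed,
        {"density_per_um3": density_per_um3, "brightness": brightness},
    )


def make_cell_phantom(
    radius_um: float = 7.5,
    shell_thickness_um: float = 0.4,
    n_shell: int = 6000,
    n_vesicles: int = 12,
    vesicle_radius_um: float = 0.25,
    seed: int = 0,
    shell_brightness: float = 80.0,
    vesicle_brightness: float = 120.0,
    emitters_per_vesicle: int = 40,
) -> Phantom:
    """Membrane-labelled cell: fluorescent spherical shell plus punctate vesicles.

    The shell emulates a plasma-membrane label (WGA-style); vesicles are
    sub-diffraction Gaussian blobs of emitters at uniform-random interior
    positions. Default 7.5 um radius, so one cell spans ~15 um of flow.
    """
    if not radius_um > shell_thickness_um > 0:
        raise ValueError("need radius > shell_thickness > 0")
    if n_shell < 0 or n_vesicles < 0 or emitters_per_vesicle < 0:
        raise ValueError("emitter counts must be non-negative")
    rng = np.random.default_rng(seed)

    # Shell: uniform directions, radii uniform in the shell volume.
    u = rng.normal(size=(n_shell, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r_in, r_out = radius_um - shell_thickness_um, radius_um
    r = (r_in**3 + (r_out**3 - r_in**3) * rng.random(n_shell)) ** (1.0 / 3.0)
    shell = u * r[:, None]

    blobs = []
    for _ in range(n_vesicles):
        # Vesicle centres uniform in the interior sphere (inside the shell).
        while True:
            c = (rng.random(3) - 0.5) * 2.0 * r_in
            if np.linalg.norm(c) <= r_in - vesicle_radius_um:
                break
        blobs.append(c + rng.normal(scale=vesicle_radius_um, size=(emitters_per_vesicle, 3)))
    pts = [shell] if n_shell else []
    bright = [np.full(n_shell, shell_brightness)] if n_shell else []
    if blobs:
        pts.append(np.vstack(blobs))
        bright.append(np.full(len(blobs) * emitters_per_vesicle, vesicle_brightness))
    em = np.column_stack([np.vstack(pts), np.concatenate(bright)])
    ext = 2.0 * (radius_um + 4.0 * vesicle_radius_um)
    return Phantom(
        em,
        "cell",
        (ext, ext, ext),
        seed,
        {
            "radius_um": radius_um,
            "shell_thickness_um": shell_thickness_um,
            "n_shell": n_shell,
            "n_vesicles": n_vesicles,
            "vesicle_radius_um": vesicle_radius_um,
        },
    )


def make_bead_phantom(
    n_beads: int,
    extent_um: tuple[float, float, float],
    min_sep_um: float,
    seed: int,
    brightness: float = 20000.0,
    max_tries: int = 10_000,
) -> Phantom:
    """Random point-bead field with a minimum pairwise separation (dart throwing).

    Used as the fixture for FWHM / resolution measurements; the default
    brightness is that of a bright calibration bead, so the Fourier support
    of the image is visible out to the optical cutoff rather than being
    noise-floor-limited.
    """
    ex, ey, ez = (float(v) for v in extent_um)
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    vol = ex * max(ey, min_sep_um) * max(ez, min_sep_um)
    if n_beads * min_sep_um**3 >= vol and min_sep_um > 0:
        raise ValueError("infeasible packing: n * min_sep^3 exceeds the extent volume")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_beads:
        tries += 1
        if tries > max_tries:
            raise ValueError("infeasible packing: dart throwing exhausted retries")
        c = (rng.random(3) - 0.5) * np.array([ex, ey, ez])
        if all(np.linalg.norm(c - p) >= min_sep_um for p in pts):
            pts.append(c)
    em = np.column_stack([np.array(pts), np.full(n_beads, brightness)])
    return Phantom(
        em,
        "beads",
        (ex, ey, ez),
        seed,
        {"n_beads": n_beads, "min_sep_um": min_sep_um, "brightness": brightness},
    )
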