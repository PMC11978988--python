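"""FrameStack: ordered raw frames plus per-frame metadata, moved as TIFF + CSV.

The TIFF holds the frames as a multi-page 32-bit float stack (axes T/Z, Y,
X); the CSV holds one row per frame with columns ``frame, time_s,
voltage_v, phase_idx, phase_rad, flow_um``. Integer TIFF input is promoted
to float with the camera gain/offset applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["FrameStack", "META_COLUMNS"]

META_COLUMNS = ["frame", "time_s", "voltage_v", "phase_idx", "phase_rad", "flow_um"]

log = logging.getLogger("fringeflow")


@dataclass
class FrameStack:
    """Ordered 2D frames (ADU) with per-frame acquisition metadata."""

    frames: np.ndarray  # (n, rows, cols) float32
    meta: pd.DataFrame  # one row per frame, META_COLUMNS
    axes: str = "TYX"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if len(self.meta) != self.frames.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.meta)}) != frame count ({self.frames.shape[0]})"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save(self, tiff_path: str | Path, csv_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        if csv_path is None:
            csv_path = tiff_path.with_suffix(".csv")
        tifffile.imwrite(
            tiff_path,
            self.frames.astype(np.float32),
            photometric="minisblack",
            metadata={"axes": self.axes},
        )
        self.meta.to_csv(csv_path, index=False)

    @classmethod
    def load(
        cls,
        tiff_path: str | Path,
        csv_path: str | Path | None = None,
        gain_e_per_adu: float = 1.0,
        offset_adu: float = 0.0,
    ) -> "FrameStack":
        """Read a TIFF + CSV pair; lossless for 32-bit float data.

        Integer-typed TIFF pages are promoted to float electrons as
        ``(adu - offset_adu) * gain_e_per_adu``; a log line flags the
        promotion. Float pages are taken verbatim.
        """
        tiff_path = Path(tiff_path)
        if csv_path is None:
            csv_path = tiff_path.with_suffix(".csv")
        arr = tifffile.imread(tiff_path)
        if arr.ndim == 2:
            arr = arr[None]
        meta = pd.read_csv(csv_path)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if arr.shape[0] != len(meta):
            raise ValueError(
                f"frame-count mismatch: TIFF has {arr.shape[0]} pages, CSV {len(meta)} rows"
            )
        if np.issubdtype(arr.dtype, np.integer):
            log.info(
                "promoting %s TIFF to float32 (gain %.3g e-/ADU, offset %.3g ADU)",
                arr.dtype,
                gain_e_per_adu,
                offset_adu,
            )
            arr = (arr.astype(np.float32) - offset_adu) * gain_e_per_adu
        return cls(arr.astype(np.float32), meta)
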