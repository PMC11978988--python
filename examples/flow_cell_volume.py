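"""Flow-scan 3D imaging of a membrane-labelled cell phantom.

A hollow fluorescent shell (plasma-membrane label) with punctate vesicles
flows at 10 um/s through the patterned light sheet while the camera runs at
50 Hz and the phase shifter cycles the three SIM phases. Every complete
phase triplet becomes one reconstructed plane; planes restack into a volume
at the native 3 x speed / frame_rate = 0.6 um spacing without registration.
"""

import numpy as np

from fringeflow.config import ExperimentConfig
from fringeflow.scenarios import run_scenario

cfg = ExperimentConfig()
cfg.phantom = {"roi_px": (176, 176)}  # 19 um field around the 15 um cell

out = run_scenario("flow_cell", cfg, seed=5)
vol = out.artifacts["volume"]

print(f"planes reconstructed : {vol.n_planes} at {vol.z_spacing_um:.2f} um native spacing")
print(f"volume z extent      : {vol.z_um[-1] - vol.z_um[0]:.1f} um "
      f"({vol.dropped_frames} incomplete frames dropped)")
tp = out.results["throughput"]
print(f"throughput           : {tp['cells_per_min']:.0f} cells/min at a 15 um cell pitch,"
      f" {tp['planes_per_cell']} planes per 15 um cell")


def extent(profile, pix, frac=0.2):
    p = profile - profile.min()
    above = np.nonzero(p > frac * p.max())[0]
    return (above[-1] - above[0]) * pix


lateral = extent(vol.xz_view.max(axis=0), vol.pixel_um)
axial = extent(vol.xz_view.max(axis=1), vol.pixel_um)
print(f"x-z section extents  : lateral {lateral:.1f} um, axial {axial:.1f} um "
      f"(ratio {axial / lateral:.2f}; 1.0 = geometry preserved)")
print("\nThe x-z view shows the shell as an annulus: equal axial and lateral")
print("extents confirm the flow-scan restacking reproduces the 3D geometry")
print("without inter-plane registration.")
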