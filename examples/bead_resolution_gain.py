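"""Resolution gain of the three-phase SIM reconstruction on synthetic beads.

Renders a field of bright sub-diffraction beads under the sinusoidal light
sheet at the three phase steps, reconstructs by band separation + Wiener
recombination, and measures the one-dimensional resolution improvement over
the widefield image from the ratio of Fourier-support cutoffs along the
modulation axis.
"""

import numpy as np

import fringeflow as ff
from fringeflow.reconstruct import NOMINAL_PHASES

cfg = ff.OpticalConfig()      # NA 1.15, 600 nm emission, 791 nm carrier
sheet = ff.LightSheetProfile()
cam = ff.CameraModel(roi_px=(256, 256))

beads = ff.make_bead_phantom(30, (24.0, 24.0, 0.0), min_sep_um=1.5, seed=1)
rng = np.random.default_rng(7)
frames = np.stack(
    [ff.render_frame(beads, cfg, sheet, cam, phi, 0.8, rng=rng) for phi in NOMINAL_PHASES]
)

rec = ff.reconstruct_triplet(
    frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu
)
gain = ff.measure_gain(rec.recon, rec.widefield, rec.pixel_recon_um, rec.pixel_um)

k0_true = 1000.0 / cfg.carrier_period_effective_nm()
print(f"carrier estimated : {rec.k0_um[0]:.4f} 1/um (nominal {k0_true:.4f})")
print(f"phases estimated  : {[f'{p % (2 * np.pi):.3f}' for p in rec.phases_est_rad]}"
      f" (commanded {[f'{p:.3f}' for p in NOMINAL_PHASES]})")
print(f"modulation depth  : {rec.m_est:.3f} (generator used 0.8)")
print(f"resolution gain   : {gain:.3f} along the modulation axis")
print(f"theoretical bound : {ff.theoretical_sim_gain(cfg):.3f} = (kc + 1/p) / kc")
print("\nA gain of ~1.33 means structures 1.33x finer than the widefield")
print("diffraction limit are transferred along the fringe direction.")
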