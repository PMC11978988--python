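"""Fringe calibration round trip on a simulated dye-filled channel.

Simulates the bench calibration: the channel is filled with a uniform
fluorescent dye, the thermal shifter is swept from 2 to 7.5 V in 0.5 V
steps (8 repetitions each), and the fringe pattern's rigid shift is tracked
through sub-pixel peak positions. The analysis recovers the fringe period,
the quadratic phase-vs-voltage coefficient, and the drive voltages that
realize the 0 / 2pi/3 / 4pi/3 phase scheme.
"""

import fringeflow as ff
from fringeflow.calibrate import calibrate_sweep

cfg = ff.OpticalConfig()          # 561 nm excitation, 791 nm measured carrier
psm = ff.PhaseShifterModel()      # generating truth: 4pi/3 at 5.86 V
sheet = ff.LightSheetProfile()
cam = ff.CameraModel(roi_px=(64, 700), frame_rate_hz=100.0)
protocol = ff.AcquisitionProtocol(mode="calibration_sweep")

ny, nx = cam.roi_px
extent = (nx * cfg.pixel_um, ny * cfg.pixel_um, 8.0)
dye = ff.make_dye_phantom(extent, density_per_um3=50.0, seed=11)

stack = ff.run_calibration_sweep(dye, cfg, sheet, psm, cam, protocol, seed=3)
result = calibrate_sweep(stack, cfg, row_band=(8, 56))

true_period_px = cfg.carrier_period_effective_nm() * 1e-3 / cfg.pixel_um
print(f"frames analysed      : {len(stack)} (12 voltages x 8 repetitions)")
print(f"fringe period        : {result.period_px:.3f} px "
      f"({result.period_nm:.1f} nm; generator used {true_period_px:.3f} px = 791 nm)")
print(f"phase coefficient    : {result.coeff_rad_per_v2:.5f} rad/V^2 "
      f"(generator: {psm.phi_ref_rad / psm.v_ref_v**2:.5f})")
print(f"solved drive voltages: {result.solved_voltages_v}")
print(f"peaks per step       : min {min(result.peaks_used)} "
      f"(>= 21 required for full confidence; low_confidence={result.low_confidence})")
print("\nThe solved 2pi/3 voltage should sit at 5.86/sqrt(2) ~ 4.14 V, the value")
print("the bench rounds to 4.15 V; period and coefficient recover the generator")
print("settings to well under 1%.")
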