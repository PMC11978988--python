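"""Thermal phase shifter: voltage-to-phase law and the 3-phase drive voltages.

The on-chip phase shifter is a resistive microheater: the optical phase it
adds is proportional to the dissipated electrical power, i.e. to V^2. With
the device anchor 4pi/3 rad at 5.86 V and zero phase at 0 V, the three-phase
structured-illumination scheme (0, 2pi/3, 4pi/3) maps to concrete drive
voltages.
"""

import math

import fringeflow as ff

psm = ff.PhaseShifterModel()

print("phase(V) = phi_ref * (V / v_ref)^2,",
      f"anchored at {psm.phi_ref_rad:.4f} rad <-> {psm.v_ref_v} V\n")

for phi, label in [(0.0, "0"), (2 * math.pi / 3, "2pi/3"), (4 * math.pi / 3, "4pi/3")]:
    v = ff.voltage_for_phase(psm, phi)
    print(f"  phase {label:>6}:  drive {v:5.2f} V")

print(
    "\nThe 2pi/3 step lands at v_ref/sqrt(2) = "
    f"{psm.v_ref_v / math.sqrt(2):.4f} V; the bench rounds it to 4.15 V."
)
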