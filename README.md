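# fringeflow

A desk-scale digital twin of an integrated optofluidic 3D imaging flow
cytometer that combines light-sheet fluorescence microscopy with structured
illumination microscopy (SIM) on a glass chip. Two waveguide outputs
interfere at a 15° semi-angle to form a sinusoidal pattern on the light
sheet; a thermal phase shifter translates the pattern; cells flow through
the sheet at constant speed, so each three-phase frame triplet is one
optical section of a 3D volume.

The package is for microscopy/instrumentation researchers who want to
prototype, calibrate and stress-test such a pipeline without the physical
chip: it simulates the raw camera frames from first principles and
implements the full analysis chain — fringe calibration, three-phase SIM
reconstruction and flow-scan volume assembly.

## The model

**Illumination.** Two coherent beams at semi-angle θ in a medium of index
*n* interfere with period *p* = λ_exc / (2 *n* sin θ). For λ_exc = 561 nm,
θ = 15° in fused silica the closed form gives 743 nm; the *measured*
carrier of the reference device, 791 nm, is the default used everywhere
downstream. The sheet intensity is *I*(x) = 1 + *m* cos(2π x/p + φ).

**Phase stepping.** The thermal shifter's phase is linear in dissipated
power, hence quadratic in voltage: φ(V) = φ_ref (V/V_ref)², anchored at
4π/3 ↔ 5.86 V and 0 at 0 V. The three-phase scheme {0, 2π/3, 4π/3} maps to
drive voltages {0, 4.14, 5.86} V.

**Reconstruction.** Each raw frame mixes the object spectrum S̃ with its
copies shifted by ±k₀ = ±1/p:
D̃_n = S̃·OTF + (m/2) e^{iφ_n} S̃(k−k₀)·OTF + (m/2) e^{−iφ_n} S̃(k+k₀)·OTF.
Solving this 3×3 system per frequency, shifting the first-order bands back
by ∓k₀ and recombining with generalized Wiener weights extends the support
along the modulation axis from k_c = 2 NA/λ_em to k_c + k₀ — a theoretical
one-dimensional resolution gain of (k_c + k₀)/k_c = 1.33 at the device
parameters (NA 1.15, λ_em 600 nm, p = 791 nm).

**Flow scanning.** At 10 µm/s and 50 Hz, each 3-frame triplet advances the
cell by 0.6 µm — the native plane spacing — giving 40 cells/min at a 15 µm
cell pitch with no moving parts and no registration.

## Worked example

`examples/bead_resolution_gain.py` renders a field of 30 bright
sub-diffraction beads under the patterned sheet, reconstructs, and measures
the gain:

```
carrier estimated : 1.2652 1/um (nominal 1.2642)
phases estimated  : ['6.244', '2.055', '4.150'] (commanded ['0.000', '2.094', '4.189'])
modulation depth  : 0.775 (generator used 0.8)
resolution gain   : 1.320 along the modulation axis
theoretical bound : 1.330 = (kc + 1/p) / kc
```

The carrier is recovered to 0.08%, the commanded phases to ~0.04 rad, and
the measured Fourier-support ratio (1.32) sits at the theoretical 1.33
bound: pattern information doubles the accessible bandwidth fraction k₀/k_c
along the fringe direction.

The other examples follow the same pattern: `phase_shifter_calibration.py`
(drive voltages for the 3-phase scheme), `fringe_calibration_roundtrip.py`
(a 12-voltage × 8-repetition dye sweep recovering period 790.8 nm and the
shifter coefficient to <0.5%), and `flow_cell_volume.py` (a 15 µm
membrane-labelled cell phantom restacked into 32 planes at 0.6 µm with an
axial/lateral extent ratio of 1.07).

A thin CLI mirrors these workflows:
`fringeflow run-scenario bead_resolution --seed 1 --out out/`, plus
`simulate-calibration`, `calibrate`, `simulate-flow`, `reconstruct`,
`assemble`.

## Layout

- `src/fringeflow/optics.py` — closed-form forward model (pattern, shifter, sheet, PSF/OTF)
- `src/fringeflow/phantoms.py` — dye / bead / membrane-labelled-cell emitter phantoms
- `src/fringeflow/acquire.py` — frame rendering and the two acquisition protocols
- `src/fringeflow/calibrate.py` — fringe-period and phase-vs-voltage calibration
- `src/fringeflow/reconstruct.py` — carrier/phase estimation, band separation, Wiener recombination, gain metrics
- `src/fringeflow/volume.py` — triplet grouping, volume restacking, throughput
- `src/fringeflow/scenarios.py`, `cli.py` — seeded end-to-end runners
- `docs/methods.md` — model assumptions, parameter choices, numerical details
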