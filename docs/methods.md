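# Methods

## Scope and coordinate conventions

fringeflow simulates and analyses a chip-integrated structured light-sheet
imaging flow cytometer. The axes are fixed throughout: **x** is the
modulation axis (the interference fringes run across it; it is also the
sheet propagation axis, so sheet thickness varies with x), **z** is the
flow/scan axis, **y** completes the camera frame. Frames are indexed
(row = y, col = x) with pixel centres on integer coordinates and the origin
at the array centre; volumes are (plane = z, y, x).

## Optical forward model

**Interference pattern.** The two beams cross at semi-angle θ = 15° defined
inside the fused-silica chip (n = 1.458), giving the closed-form period
p = λ_exc/(2 n sin θ) = 743 nm at 561 nm. The device's measured period,
791 nm, is the default carrier for every simulation and reconstruction
(`OpticalConfig.carrier_period_nm`); setting it to `None` switches to the
closed form. The reference device also quotes a theoretical 754 nm that no
standard refractive index reproduces with this formula; the package records
the two values it can ground (743 nm closed-form, 791 nm measured) and
standardizes on the measured one. The illumination is
I(x) = 1 + m cos(2π x/p + φ) with modulation depth m ∈ [0, 1], default 0.8
(the raw fringe images of the device show imperfect contrast; the exact
value is not published and all reconstruction math works for any m in
(0, 1]).

**Phase shifter.** The microheater's optical phase is linear in dissipated
power and therefore quadratic in drive voltage at constant resistance:
φ(V) = φ_offset + φ_ref (V/V_ref)², anchored at φ_ref = 4π/3 ↔ 5.86 V with
φ(0) = 0. The measured 0.18% peak-to-peak electrical stability is carried
as documentation (`drift_ppk`) and not simulated by default; an optional
multiplicative power jitter per frame (`power_jitter_frac`) exists for
robustness studies.

**Light sheet.** The real hollow-lens profile is unpublished, so the sheet
thickness follows the Gaussian-beam law anchored at the 1.1 µm focal FWHM:
w₀ = FWHM/√(2 ln 2), z_R = π w₀² n_medium/λ_exc ≈ 6.5 µm, FWHM(x) =
1.1·√(1 + (x/z_R)²) µm. At ±20 µm this predicts 3.55 µm against the lens
design's 3.4/3.2 µm — within 10% of 3.4 µm and of the pair's mean. A
symmetric Gaussian cannot reproduce the design's slight asymmetry; the
model is treated as accurate to ~10% away from focus. The axial weight of
an emitter is a Gaussian in its distance from the sheet plane along z, with
the FWHM evaluated at the emitter's x. The weight is not renormalized by
thickness, so a thicker sheet integrates more of a volumetric sample — for
the uniform dye this produces exactly the smooth envelope the calibration
high-pass is designed to remove.

**Detection.** Widefield imaging through a 1.15 NA objective at 60× total
magnification onto 6.5 µm camera pixels (object pixel 108.3 nm). The
incoherent OTF is the analytic pupil autocorrelation ("chat" function) with
cutoff k_c = 2 NA/λ_em = 3.83 µm⁻¹ at the 600 nm emission proxy; the PSF is
its inverse transform. The raw pixel satisfies Nyquist for k_c (0.83 of the
limit) but not for the extended SIM cutoff k_c + k₀ = 5.10 µm⁻¹; the
reconstruction therefore lives on a 2× zero-padded grid (54.2 nm pixels),
which is standard SIM practice. `validate_sampling` reports both checks
separately.

## Synthetic phantoms — what they emulate and what they do not

All generators are pure functions of (parameters, seed), with brightness in
expected photons per frame at the sheet focus.

- **Dye** (calibration): homogeneous Poisson point process, default
  50 emitters/µm³ at 50 photons each. A rhodamine solution is effectively a
  continuum; at sparse densities the emitter-count speckle acts as a fixed
  intensity texture that anchors fringe peaks and attenuates the measured
  shifts — an artifact of discretization, not of the physical system. At
  50/µm³ the residual speckle contributes <0.1% bias to the recovered
  period.
- **Cell**: membrane-labelled phantom — 6000 emitters on a spherical shell
  (radius 7.5 µm, thickness 0.4 µm) plus 12 punctate vesicles (Gaussian
  blobs, σ = 0.25 µm, sub-diffraction to exercise the resolution gain).
  Cell size is not published for the reference experiment; 7.5 µm radius
  makes one cell span ≈15 µm of flow, consistent with the quoted
  throughput. No deformation in flow, no Brownian motion, no optical
  heterogeneity (scattering/absorption).
- **Beads**: dart-thrown point emitters with a minimum pairwise separation,
  default 20 000 photons/frame (a bright calibration bead). The resolution
  measurement presumes the low-noise regime: at dim settings the
  Fourier-support metric is noise-floor-limited and measures SNR rather
  than resolution (the package warns in that case).

Because the phantoms are ideal point-emitter scenes under an aberration-free
shift-invariant PSF with exactly known noise, passing tests demonstrate the
*pipeline's* correctness and calibration — not performance on real tissue,
where wall-roughness illumination stripes, aberrations, background and
labelling variability would all reduce the measured quantities.

## Acquisition simulation

Emitter signal = brightness × sheet weight × pattern intensity at the
emitter's true x; emitters are binned to the nearest pixel and the expected
image convolved with the PSF via FFT (adequate at 108 nm pixels; no
per-pixel analytic integration). Camera: electrons = Poisson(QE × photons)
plus Gaussian read noise (1.6 e⁻ RMS, sCMOS-like), then gain (0.46 e⁻/ADU)
and offset (100 ADU). Noise can be disabled for oracle tests; the
expectation is deterministic and linear in the phantom.

The two crossed sheets are modelled as a single effective sheet carrying
the pattern — their overlap defines the image plane — and the per-sheet 15°
tilt is folded into the pattern rather than ray-traced. No motion blur
within an exposure, no photobleaching, no Fabry–Perot or speckle effects.

Protocols: **calibration sweep** — one frame per voltage (2 → 7.5 V in
0.5 V steps; that enumeration yields 12 values although the reference
protocol counts 11) × 8 repetitions at 100 Hz, repetition-major;
**flow scan** — frames at 1/frame_rate with the phase cycling through the
three drive voltages; each complete (0, 1, 2) triplet is one plane at the
mean flow position of its frames (intra-triplet motion of 0.4 µm at
defaults is an acknowledged, modelled artifact).

## Fringe calibration

Per voltage: repetition average → column-mean line profile over a uniform
band → spectral high-pass → sub-pixel peaks → matched shifts.

- **High-pass**: raised-cosine spectral mask, zero below 0.3× the expected
  carrier with a transition of half the cutoff width; removes the sheet
  envelope and DC exactly while preserving carrier amplitude within 2%.
- **Peaks**: `scipy.signal.find_peaks` with a prominence floor of 10% of
  the profile maximum, refined by 3-point parabolic interpolation. The
  parabola has an oscillating per-peak bias up to ~0.02 px on a 7.3
  px/period carrier; it averages out over the >20 peaks each step uses.
- **Shifts**: nearest-neighbour peak matching between consecutive voltages,
  discarding unmatched edge peaks; steps whose median displacement exceeds
  0.45 periods are refused as ambiguous (matching aliases at half a
  period). The pooled mean inter-peak spacing gives the period; cumulative
  phase = 2π × cumulative shift / period, sign-fixed so phase grows with
  voltage.
- **Fit**: least squares of phase = a·(V² − V_first²). The measured
  cumulative phase is necessarily zero at the first swept voltage while the
  physical law is anchored at 0 V; subtracting the anchor term makes the
  two consistent (with data starting at 0 V this reduces to a·V²). Solved
  drive voltages √(φ/a) are reported to 0.01 V. Results with fewer than 21
  matched peaks at any step are flagged low-confidence.

With the default generator (64 × 700 ROI, default noise, 8 repetitions) the
period and coefficient are recovered to well under 1% and the solved 2π/3
voltage to within ~0.01 V of the generating 4.1436 V.

## SIM reconstruction

Single orientation, three phases — 1D super-resolution exactly as the
device provides.

- **Band separation**: per-frequency inverse of the 3×3 mixing matrix with
  rows [1, (m/2)e^{iφₙ}, (m/2)e^{−iφₙ}]; condition number above 10⁶
  (coincident phases) is refused. Equally spaced phases give the DFT-like,
  best-conditioned matrix.
- **Carrier**: the separated first-order band times the conjugate
  zeroth-order band in real space has a Fourier coefficient whose magnitude
  peaks at k₀; the peak is located on the grid within ±15% of the nominal
  carrier (calibration provides a strong prior) and refined continuously by
  bounded scalar maximization. The search runs along x only (fringes are
  axis-aligned by construction; the hardware tolerance is ±2°).
- **Phases**: each frame's complex carrier coefficient
  Yₙ = Σ_x Dₙ(x) e^{−2πi k₀·x} decomposes as Z + A e^{iφₙ} + B e^{−iφₙ}
  with Z, A, B common to the triplet (Z absorbs the zeroth-order content
  and any constant camera offset). Solving across the three frames with the
  nominal phase factors and taking the argument of each residual
  first-order term is exact for a balanced triple — the sample's
  non-negativity makes A real and positive, fixing the absolute reference —
  and degrades only to first order for small deviations. Naive correlation
  estimators carry a 1/√N bias from the conjugate band on sparse scenes;
  this solve avoids it. Modulation depth m = 2|A|/(total flux × OTF(k₀)).
- **Recombination**: bands are zero-padded 2×, the first orders shifted by
  ∓k₀ via sub-pixel real-space phase ramps, combined with generalized
  Wiener weights OTF*ᵢ/(Σ OTFᵢ² + w²), apodized by a radial triangle window
  to k_c + |k₀|, and inverse-transformed. Default w = 0.05 relative to the
  unit-normalized OTF (configurable; the reference device publishes
  neither w nor the apodization). The output is divided by the analytic
  Wiener DC transfer so its mean equals the widefield mean for any content
  — a content-based rescale would be unstable on nearly-empty planes.
  Negative values are retained internally and clipped at zero only on
  export (recorded in the result metadata).
- **Gain measurement**: default `fourier_cutoff` — each image's spectral
  magnitude profile along k_x (averaged over |k_y| ≤ 0.5 µm⁻¹, lightly
  smoothed, DC-normalized) is thresholded at a single fixed floor, 3× the
  median of the widefield's own empty high-frequency band; the gain is the
  ratio of the largest frequencies above the floor. The metric is valid in
  the low-noise regime; when the widefield support is noise-floor-limited
  (below 0.8 k_c) a warning states that the ratio then measures SNR, not
  resolution — in that regime a support ratio *rises* with noise because
  the carrier offset k₀ is additive, so "gain degrades with noise" is not a
  property any support-ratio metric can have. Degradation with noise is
  instead guaranteed (and tested) for reconstruction fidelity. A
  `bead_fwhm` mode (ratio of mean bead FWHMs along x) is provided as a
  secondary metric; it conflates Wiener sharpening with true support
  extension and typically reads higher than the Fourier ratio.

At the device parameters the theoretical gain is (k_c + k₀)/k_c = 1.330 and
the measured Fourier-support ratio on default bead triplets is 1.32 ± 0.01.

## Volume assembly and throughput

Complete (0, 1, 2) triplets are reconstructed independently and restacked
at the native spacing 3 × speed/frame_rate (0.6 µm at 10 µm/s, 50 Hz); the
sheet at lab z = 0 samples the moving cell at sample coordinate −flow, so
planes are re-sorted to increasing z. No registration is applied, mirroring
the flow stability of the integrated device; a 1D cross-correlation drift
check per plane is reported but never applied (planes with too little
structure report 0). The x–z view resamples the central row of every plane
with z linearly interpolated to isotropic display pixels. Note the device's
published "selected planes at 1.1 µm" is a display subset; the native
triplet spacing at the stated flow and frame rates is 0.6 µm, and both
numbers are exposed rather than reconciled. Throughput: cells/min =
60 × speed/(cell extent + gap); planes/cell = floor(extent/spacing) —
40 cells/min at a 15 µm pitch, 15 planes for a 9 µm-extent cell at 0.6 µm.

## Reproducibility and problem sizes

All randomness flows from one global seed through named substreams (stage
name hashed into the `SeedSequence` spawn key), so stages re-run
independently and identically. Default desk-scale sizes: calibration uses a
64 × 700 ROI (the analysis band uses the central rows; the 700-column width
preserves the ≥20-peak geometry of the full 512 × 700 frame), bead
resolution uses 256 × 256 frames, the flow-cell volume a 176 × 176 field —
each chosen as the smallest size that leaves the relevant statistic
generator-limited rather than window-limited.

## Known limitations

- Single fringe orientation: resolution improves along x only; the volume
  stays widefield-limited in y and sheet/step-limited in z.
- No blind or iterative SIM, no deconvolution beyond Wiener recombination,
  no stripe-artifact removal, no aberrations or field-dependent PSF.
- The phase estimator is exact at balanced triples but attenuates large
  per-frame phase deviations (~1/3 cross-talk); the device's rounding of
  4.1436 V to 4.15 V (0.006 rad) is far below where this matters.
- Fabrication physics (etching, waveguide losses, switching dynamics,
  long-term drift) is out of scope; the 0.18% stability figure is carried
  as documentation only.
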