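"""Three-phase SIM reconstruction: band separation, carrier/phase estimation,
Wiener recombination and resolution metrics."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import fringeflow as ff
from fringeflow.phantoms import Phantom
from fringeflow.reconstruct import (
    NOMINAL_PHASES,
    _cfft2,
    _chat_otf,
    _cifft2,
    _freq_grids,
    separate_bands,
)

K0_UM = 1000.0 / 791.0


def _forward_triplet(S, cfg, phases=NOMINAL_PHASES, m=0.8, k0=K0_UM):
    """Analytic forward model: patterned excitation then OTF blur (no noise)."""
    n = S.shape[1]
    x_um = (np.arange(n) - n // 2) * cfg.pixel_um
    ky, kx = _freq_grids(S.shape, cfg.pixel_um)
    otf = _chat_otf(np.hypot(ky, kx), cfg.cutoff_um)
    frames = [
        _cifft2(_cfft2(S * (1 + m * np.cos(2 * np.pi * k0 * x_um[None, :] + p))) * otf).real
        for p in phases
    ]
    return np.stack(frames), otf, x_um


@pytest.fixture(scope="module")
def smooth_object(cfg):
    rng = np.random.default_rng(0)
    return gaussian_filter(rng.uniform(0.0, 1.0, (64, 64)), 1.5)


class TestWidefield:
    def test_identical_frames_pass_through(self):
        f = np.random.default_rng(1).random((32, 32))
        assert np.allclose(ff.widefield_from_triplet(np.stack([f, f, f])), f)

    @pytest.mark.parametrize("m", [0.3, 0.8, 1.0])
    def test_balanced_phases_cancel_modulation(self, cfg, smooth_object, m):
        frames, otf, _ = _forward_triplet(smooth_object, cfg, m=m)
        unmod = _cifft2(_cfft2(smooth_object) * otf).real
        resid = np.abs(frames.mean(axis=0) - unmod).max() / unmod.max()
        assert resid < 1e-6

    def test_unbalanced_phases_leave_residual(self, cfg, smooth_object):
        frames, otf, _ = _forward_triplet(smooth_object, cfg, phases=(0.0, np.pi / 2, np.pi))
        unmod = _cifft2(_cfft2(smooth_object) * otf).real
        resid = np.abs(frames.mean(axis=0) - unmod).max() / unmod.max()
        assert resid > 0.01


class TestBandSeparation:
    def test_oracle_equivalence_on_64px_grid(self, cfg, smooth_object):
        # brute-force-constructed ground-truth bands (complex forward FFTs)
        m = 0.77
        frames, otf, x_um = _forward_triplet(smooth_object, cfg, m=m)
        bands = separate_bands(frames, NOMINAL_PHASES, m=m)
        cfftc = lambda a: np.fft.fftshift(np.fft.fft2(a))
        ramp = np.exp(2j * np.pi * K0_UM * x_um)[None, :]
        truths = [
            cfftc(smooth_object) * otf,
            cfftc(smooth_object * ramp) * otf,
            cfftc(smooth_object * np.conj(ramp)) * otf,
        ]
        for band, truth in zip(bands, truths):
            assert np.abs(band - truth).max() / np.abs(truth).max() < 1e-6

    def test_degenerate_phases_rejected(self, smooth_object, cfg):
        frames, _, _ = _forward_triplet(smooth_object, cfg)
        with pytest.raises(ValueError):
            separate_bands(frames, (0.0, 0.0, 2.0))

    def test_equally_spaced_phases_are_best_conditioned(self):
        def cond(phases, m=1.0):
            mix = np.stack(
                [
                    np.ones(3, dtype=complex),
                    (m / 2) * np.exp(1j * np.asarray(phases)),
                    (m / 2) * np.exp(-1j * np.asarray(phases)),
                ],
                axis=1,
            )
            return np.linalg.cond(mix)

        balanced = cond(NOMINAL_PHASES)
        rng = np.random.default_rng(5)
        for _ in range(20):
            other = np.sort(rng.uniform(0, 2 * np.pi, 3))
            assert balanced <= cond(other) + 1e-9


class TestCarrierEstimation:
    def test_carrier_recovered_noise_free(self, cfg, sheet):
        cam = ff.CameraModel(roi_px=(256, 256))
        ph = ff.make_bead_phantom(30, (24, 24, 0), 1.5, seed=1)
        frames = np.stack(
            [ff.render_frame(ph, cfg, sheet, cam, p, 0.8, noise=False) for p in NOMINAL_PHASES]
        )
        (kx, ky), phases, m = ff.estimate_carrier_crosscorr(
            frames, cfg, offset_adu=cam.offset_adu
        )
        assert abs(kx - K0_UM) / K0_UM < 0.005
        err = np.array(phases) - np.array(NOMINAL_PHASES)
        err = (err + np.pi) % (2 * np.pi) - np.pi
        assert np.abs(err).max() < 0.05
        assert m == pytest.approx(0.8, abs=0.1)

    def test_phase_rms_under_default_noise(self, cfg, sheet):
        cam = ff.CameraModel(roi_px=(128, 128))
        errs = []
        for seed in range(20):
            ph = ff.make_bead_phantom(15, (12, 12, 0), 1.2, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            frames = np.stack(
                [ff.render_frame(ph, cfg, sheet, cam, p, 0.8, rng=rng) for p in NOMINAL_PHASES]
            )
            _, phases, _ = ff.estimate_carrier_crosscorr(frames, cfg, offset_adu=cam.offset_adu)
            e = np.array(phases) - np.array(NOMINAL_PHASES)
            errs.extend(((e + np.pi) % (2 * np.pi) - np.pi).tolist())
        assert np.sqrt(np.mean(np.square(errs))) < 0.15

    def test_no_modulation_raises(self, cfg, sheet, cam_small):
        ph = ff.make_bead_phantom(10, (10, 10, 0), 1.0, seed=2)
        frames = np.stack(
            [ff.render_frame(ph, cfg, sheet, cam_small, p, 0.0, noise=False) for p in NOMINAL_PHASES]
        )
        with pytest.raises(ValueError):
            ff.estimate_carrier_crosscorr(frames, cfg, offset_adu=cam_small.offset_adu)


class TestRecombination:
    def test_invalid_wiener_parameter(self, cfg, smooth_object):
        frames, _, _ = _forward_triplet(smooth_object, cfg)
        bands = separate_bands(frames, NOMINAL_PHASES, m=0.8)
        with pytest.raises(ValueError):
            ff.recombine_wiener(bands, (K0_UM, 0.0), cfg, wiener_w=0.0)

    def test_fourier_support_extends_to_extended_cutoff(self, cfg, bead_triplet):
        frames, cam, _ = bead_triplet
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu
        )
        spec = np.abs(_cfft2(rec.recon))
        ny, nx = spec.shape
        kx = np.fft.fftshift(np.fft.fftfreq(nx, d=rec.pixel_recon_um))
        row = spec[ny // 2 - 2 : ny // 2 + 3].mean(axis=0)
        k_ext = cfg.cutoff_um + rec.k0_um[0]
        dk = kx[1] - kx[0]
        support = np.abs(kx[row > 1e-9 * row.max()])
        assert support.max() == pytest.approx(k_ext, abs=2 * dk)

    def test_energy_conservation(self, cfg, bead_triplet):
        frames, cam, _ = bead_triplet
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu
        )
        assert rec.recon.mean() == pytest.approx(rec.widefield.mean(), rel=0.05)

    def test_two_beads_resolved_only_after_reconstruction(self, cfg, sheet):
        # 300 nm pair: below the widefield Rayleigh limit (~318 nm), above the
        # extended one
        cam = ff.CameraModel(roi_px=(128, 128))
        em = np.array([[-0.15, 0.0, 0.0, 20000.0], [0.15, 0.0, 0.0, 20000.0]])
        ph = Phantom(em, "beads", (2, 2, 0), 0)
        frames = np.stack(
            [ff.render_frame(ph, cfg, sheet, cam, p, 0.8, noise=False) for p in NOMINAL_PHASES]
        )
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu,
            k0_um=(K0_UM, 0.0), modulation_depth=0.8,
        )

        def dip(img):
            from scipy.signal import find_peaks

            line = img[img.shape[0] // 2]
            c = img.shape[1] // 2
            seg = line[c - 10 : c + 11] - line.min()
            pk, _ = find_peaks(seg)
            if len(pk) < 2:
                return 0.0
            two = sorted(sorted(pk, key=lambda i: -seg[i])[:2])
            valley = seg[two[0] : two[1] + 1].min()
            return 1 - valley / min(seg[two[0]], seg[two[1]])

        assert dip(rec.widefield_up) < 0.05
        assert dip(rec.recon) >= 0.20


class TestGainMeasurement:
    def test_identical_images_give_unit_gain(self, cfg, bead_triplet):
        frames, cam, _ = bead_triplet
        wf = frames.mean(axis=0) - cam.offset_adu
        assert ff.measure_gain(wf, wf, cfg.pixel_um, cfg.pixel_um) == pytest.approx(1.0)

    def test_gain_matches_on_default_beads(self, cfg, bead_triplet):
        frames, cam, _ = bead_triplet
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu
        )
        g = ff.measure_gain(rec.recon, rec.widefield, rec.pixel_recon_um, rec.pixel_um)
        assert g == pytest.approx(1.33, abs=0.05)
        assert g <= ff.theoretical_sim_gain(cfg) + 0.02

    def test_reconstruction_fidelity_degrades_monotonically_with_read_noise(self, cfg, sheet):
        # median RMS deviation from the noise-free reconstruction is
        # non-decreasing across three read-noise levels (10 seeds each)
        def reconstruct(frames, cam):
            return ff.reconstruct_triplet(
                frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu,
                k0_um=(K0_UM, 0.0), modulation_depth=0.8,
            ).recon

        med = []
        for rn in (1.6, 30.0, 120.0):
            cam = ff.CameraModel(roi_px=(128, 128), read_noise_e=rn)
            errs = []
            for seed in range(10):
                ph = ff.make_bead_phantom(12, (12, 12, 0), 1.2, seed=seed, brightness=3000.0)
                clean = np.stack(
                    [
                        ff.render_frame(ph, cfg, sheet, cam, p, 0.8, noise=False)
                        for p in NOMINAL_PHASES
                    ]
                )
                ref = reconstruct(clean, cam)
                rng = np.random.default_rng(seed)
                noisy = np.stack(
                    [ff.render_frame(ph, cfg, sheet, cam, p, 0.8, rng=rng) for p in NOMINAL_PHASES]
                )
                rec = reconstruct(noisy, cam)
                errs.append(np.sqrt(np.mean((rec - ref) ** 2)) / ref.std())
            med.append(np.median(errs))
        assert med[0] <= med[1] <= med[2]

    def test_noise_floor_limited_gain_warns(self, cfg, sheet):
        # at very dim signal the support ratio is SNR-limited and flagged
        cam = ff.CameraModel(roi_px=(128, 128))
        ph = ff.make_bead_phantom(12, (12, 12, 0), 1.2, seed=0, brightness=150.0)
        rng = np.random.default_rng(0)
        frames = np.stack(
            [ff.render_frame(ph, cfg, sheet, cam, p, 0.8, rng=rng) for p in NOMINAL_PHASES]
        )
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu,
            k0_um=(K0_UM, 0.0), modulation_depth=0.8,
        )
        with pytest.warns(UserWarning, match="noise-floor-limited"):
            ff.measure_gain(
                rec.recon, rec.widefield, rec.pixel_recon_um, rec.pixel_um, cfg=cfg
            )

    def test_bead_fwhm_mode(self, cfg, bead_triplet):
        frames, cam, _ = bead_triplet
        rec = ff.reconstruct_triplet(
            frames, cfg, commanded_phases=NOMINAL_PHASES, offset_adu=cam.offset_adu
        )
        g = ff.measure_gain(
            rec.recon, rec.widefield_up, rec.pixel_recon_um, rec.pixel_recon_um,
            method="bead_fwhm",
        )
        assert g > 1.0
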