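"""Contour tracking, fluctuation statistics, stiffness estimators, GUV fit."""

import numpy as np
import pytest

from memdiv.flicker import (
    ContourSeries,
    SegmentationConfig,
    effective_stiffness,
    fluctuation_map,
    guv_bending_modulus,
    layered_scaling,
    segment_contours,
)
from memdiv.synthetic import (
    ActiveNoiseConfig,
    OpticsConfig,
    gen_contour_series,
    gen_guv_modes,
    gen_image_stack,
)


def _smooth_series(seed=0, n=128, nf=40, radius_um=1.0, mode_sd=8.0):
    """Low-mode fluctuation field: smooth along arclength, known moments."""
    theta = 2.0 * np.pi * np.arange(n) / n
    rng = np.random.default_rng(seed)
    h = np.zeros((n, nf))
    for m in range(2, 9):
        a = rng.normal(0.0, mode_sd, nf)
        b = rng.normal(0.0, mode_sd, nf)
        h += np.outer(np.cos(m * theta), a) + np.outer(np.sin(m * theta), b)
    return ContourSeries(h=h, x=theta, fiducial_radius=radius_um)


class TestFluctuationMap:
    def test_gaussian_series_has_reference_moments(self):
        """i.i.d. Gaussian sites: sigma ~ 10 nm, S ~ 0, kurtosis ~ 3."""
        rng = np.random.default_rng(0)
        ser = ContourSeries(
            h=rng.normal(0.0, 10.0, (128, 4000)), x=np.zeros(128)
        )
        fm = fluctuation_map(ser)
        nf = 4000
        # moment-estimator SEs for a Gaussian: sd/sqrt(2n), sqrt(6/n),
        # sqrt(24/n); the 128-site maximum needs a wider band than one
        # site's 3 SE (expected max |z| over 128 draws is ~2.9)
        assert np.abs(fm.sigma_h - 10.0).mean() < 3 * 10.0 / np.sqrt(2 * nf)
        assert np.all(np.abs(fm.sigma_h - 10.0) < 4.5 * 10.0 / np.sqrt(2 * nf))
        assert np.all(np.abs(fm.skew) < 4.5 * np.sqrt(6.0 / nf))
        assert np.all(np.abs(fm.kurt - 3.0) < 4.5 * np.sqrt(24.0 / nf))
        assert np.all(fm.label == "stiff")

    def test_burst_noise_raises_kurtosis_and_labels_soft(self):
        ser = gen_contour_series(
            200.0, np.pi * 3.0, seed=3,
            active=ActiveNoiseConfig(soft_fraction=0.25),
        )
        fm = fluctuation_map(ser)
        n_soft = int((fm.label == "soft").sum())
        assert n_soft >= 0.6 * 0.25 * 128
        assert fm.kurt[fm.label == "soft"].mean() > 3.5

    def test_constant_series_flagged_degenerate(self):
        h = np.zeros((4, 200))
        h[1] = 5.0   # constant but nonzero
        fm = fluctuation_map(ContourSeries(h=h, x=np.zeros(4)))
        assert fm.degenerate.all()
        assert np.all(fm.skew == 0.0)
        assert np.all(fm.kurt == 3.0)


class TestEffectiveStiffness:
    def test_untreated_cell_reference_value(self, cell_area):
        """Sigma = 220 nm on A = pi*1*3 um^2 gives ~200 kBT."""
        est = effective_stiffness(220.0, cell_area)
        assert est.K_eff == pytest.approx(194.7, abs=0.1)
        assert round(est.K_eff, -2) == 200.0

    def test_inverse_square_law(self, cell_area):
        k1 = effective_stiffness(100.0, cell_area).K_eff
        k2 = effective_stiffness(200.0, cell_area).K_eff
        assert k1 == pytest.approx(4.0 * k2)

    def test_softer_map_means_lower_stiffness(self, cell_area):
        k0 = effective_stiffness(220.0, cell_area).K_eff
        assert effective_stiffness(300.0, cell_area).K_eff < k0
        assert effective_stiffness(150.0, cell_area).K_eff > k0

    def test_equipartition_closure_across_stiffness_grid(self, cell_area):
        """Generated contours at K in {50,100,200,400} recover K within 5%."""
        for K in (50.0, 100.0, 200.0, 400.0):
            ser = gen_contour_series(K, cell_area, seed=int(K))
            est = effective_stiffness(fluctuation_map(ser), cell_area)
            assert est.K_eff == pytest.approx(K, rel=0.05)

    def test_mean_of_sd_variant_is_smaller_or_equal(self, cell_area):
        ser = gen_contour_series(200.0, cell_area, seed=5)
        fm = fluctuation_map(ser)
        canonical = effective_stiffness(fm, cell_area)
        variant = effective_stiffness(fm, cell_area, mean_of_sd=True)
        assert variant.Sigma <= canonical.Sigma  # Jensen

    def test_zero_amplitude_is_an_error(self, cell_area):
        with pytest.raises(ValueError):
            effective_stiffness(0.0, cell_area)
        fm = fluctuation_map(
            ContourSeries(h=np.zeros((4, 100)), x=np.zeros(4))
        )
        with pytest.raises(ValueError):
            effective_stiffness(fm, cell_area)


class TestLayeredScaling:
    def test_single_bilayer_is_identity(self):
        assert layered_scaling(12.0, 5.0, 5.0) == pytest.approx(12.0)

    def test_fourfold_wall_gives_sixteenfold_stiffness(self):
        assert layered_scaling(12.0, 20.0, 5.0) == pytest.approx(192.0)

    def test_measured_wall_thickness(self):
        assert layered_scaling(12.0, 21.0, 5.0) == pytest.approx(211.7, abs=0.1)

    def test_thin_wall_rejected(self):
        with pytest.raises(ValueError):
            layered_scaling(12.0, 3.0, 5.0)


class TestSegmentation:
    def test_subpixel_accuracy_on_noiseless_halos(self):
        """Boundary offsets swept on a sub-px grid: RMS error <= 5 nm."""
        opt = OpticsConfig(n_frames=1)
        errs = []
        for off in np.arange(0.0, 1.0, 0.04):
            r_um = (20.0 + off) * opt.pixel_size / 1000.0
            ser = ContourSeries(h=np.zeros((128, 1)), x=np.zeros(128),
                                fiducial_radius=r_um)
            stack = gen_image_stack(ser, opt, shape=(96, 96))
            rec = segment_contours(stack, (47.5, 47.5, 20.0))
            rec_px = float(np.mean(np.atleast_1d(rec.fiducial_radius))) \
                * 1000.0 / opt.pixel_size
            errs.append((rec_px - (20.0 + off)) * opt.pixel_size)
        assert np.sqrt(np.mean(np.square(errs))) <= 5.0

    def test_error_grows_with_image_noise(self):
        opt0 = OpticsConfig(n_frames=1)
        ser = ContourSeries(h=np.zeros((128, 1)), x=np.zeros(128),
                            fiducial_radius=1.0)
        rms = []
        for noise in (0.0, 2.0, 8.0):
            stack = gen_image_stack(
                ser, OpticsConfig(n_frames=1, noise_sd=noise),
                seed=9, shape=(100, 100),
            )
            rec = segment_contours(stack, (49.5, 49.5, 20.0))
            r_nm = np.atleast_1d(rec.fiducial_radius) * 1000.0
            rms.append(np.sqrt(np.mean((r_nm - 1000.0) ** 2)))
        assert rms[0] <= 0.1 * opt0.pixel_size  # <= 0.1 px at zero noise
        assert rms[0] < rms[1] < rms[2]

    def test_integer_translation_leaves_field_invariant(self):
        """Rigidly shifting the whole stack changes nothing after the
        tracker's drift correction."""
        ser = _smooth_series(seed=1)
        stack = gen_image_stack(ser, OpticsConfig(n_frames=ser.n_frames),
                                shape=(116, 116))
        shifted = np.roll(stack, shift=(4, -3), axis=(1, 2))
        a = segment_contours(stack, (57.5, 57.5, 20.0))
        b = segment_contours(shifted, (57.5, 57.5, 20.0))
        assert np.sqrt(np.mean((a.h - b.h) ** 2)) < 1.0  # nm

    def test_subpixel_recenter_keeps_sigma_within_one_percent(self):
        """Re-rendering the same cell off pixel centers changes Sigma < 1%."""
        ser = _smooth_series(seed=0)
        opt = OpticsConfig(n_frames=ser.n_frames)
        s0 = gen_image_stack(ser, opt, shape=(110, 110),
                             center=(54.5, 54.5))
        s1 = gen_image_stack(ser, opt, shape=(110, 110),
                             center=(52.3, 58.2))
        f0 = fluctuation_map(segment_contours(s0, (54.5, 54.5, 20.0)))
        f1 = fluctuation_map(segment_contours(s1, (54.5, 54.5, 20.0)))
        S0 = np.sqrt((f0.sigma_h**2).mean())
        S1 = np.sqrt((f1.sigma_h**2).mean())
        assert abs(S0 - S1) / S0 < 0.01

    def test_standing_mode_amplitude_recovered_at_snr_twenty(self):
        """A 20 nm standing sinusoidal mode survives the render-track
        round trip within 10% at SNR 20 (halo peak / noise SD).

        At this noise level the per-ray localization error exceeds the
        mode amplitude, so the amplitude is read off the contour's
        Fourier-mode variance after subtracting the white noise floor
        estimated from signal-free high modes — the standard procedure in
        flicker spectroscopy.
        """
        n, nf = 128, 50
        theta = 2.0 * np.pi * np.arange(n) / n
        h = 20.0 * np.outer(
            np.sin(3.0 * theta), np.sin(2.0 * np.pi * np.arange(nf) / nf)
        )
        ser = ContourSeries(h=h, x=theta, fiducial_radius=1.0)
        stack = gen_image_stack(
            ser, OpticsConfig(n_frames=nf, noise_sd=10.0), seed=4,
            shape=(110, 110),
        )
        rec = segment_contours(stack, (54.5, 54.5, 20.0))

        def quad_var(hh, m, fn):
            return ((2.0 / n) * (hh.T @ fn(m * theta))).var()

        var3 = quad_var(rec.h, 3, np.sin)
        floor = np.mean(
            [quad_var(rec.h, m, np.sin) + quad_var(rec.h, m, np.cos)
             for m in range(15, 40)]
        ) / 2.0
        amp_rec = np.sqrt(2.0 * max(var3 - floor, 0.0))
        amp_true = np.sqrt(2.0 * quad_var(h, 3, np.sin))
        assert amp_true == pytest.approx(20.0, rel=1e-6)
        assert amp_rec == pytest.approx(amp_true, rel=0.10)

    def test_pipeline_closure_per_site_sigma(self):
        """Render a known fluctuation field, track it back: per-site sigma
        within 10% (optics-limited)."""
        ser = _smooth_series(seed=0)
        stack = gen_image_stack(ser, OpticsConfig(n_frames=ser.n_frames),
                                shape=(110, 110))
        rec = segment_contours(stack, (54.5, 54.5, 20.0))
        s_true = fluctuation_map(ser).sigma_h
        s_rec = fluctuation_map(rec).sigma_h
        assert np.max(np.abs(s_rec - s_true) / s_true) < 0.10

    def test_lost_contour_frames_are_flagged(self):
        """Frames with no halo contrast are excluded with a flag."""
        ser = ContourSeries(h=np.zeros((128, 3)), x=np.zeros(128),
                            fiducial_radius=1.0)
        stack = gen_image_stack(ser, OpticsConfig(n_frames=3),
                                shape=(100, 100))
        stack[1] = 20.0   # blank frame: halo gone
        cfg = SegmentationConfig(min_gradient=1.0)
        rec = segment_contours(stack, (49.5, 49.5, 20.0), cfg)
        assert list(rec.flagged_frames) == [1]
        assert rec.n_frames == 2


class TestGuvFit:
    AREA = float(np.pi * 4.0 * 100.0)   # sphere of radius 10 um

    def test_recovery_from_equipartition_spectrum(self):
        """kappa = 12 kBT recovered within 2 kBT at 2000 frames."""
        amps, q = gen_guv_modes(12.0, 0.0, self.AREA, n_modes=20,
                                n_frames=2000, seed=7)
        fit = guv_bending_modulus(amps, q, self.AREA)
        assert fit.kappa == pytest.approx(12.0, abs=2.0)
        assert not fit.weak_kappa

    def test_doubling_kappa_halves_high_q_variance(self):
        a1, q = gen_guv_modes(12.0, 0.0, self.AREA, seed=1)
        a2, _ = gen_guv_modes(24.0, 0.0, self.AREA, seed=1)
        v1 = np.mean(np.abs(a1[-5:]) ** 2)
        v2 = np.mean(np.abs(a2[-5:]) ** 2)
        assert v1 / v2 == pytest.approx(2.0, rel=0.05)

    def test_tension_dominated_spectrum_flags_weak_kappa(self):
        amps, q = gen_guv_modes(0.01, 500.0, self.AREA, n_modes=12,
                                n_frames=800, seed=2)
        fit = guv_bending_modulus(amps, q, self.AREA)
        assert fit.weak_kappa

    def test_input_size_preconditions(self):
        amps, q = gen_guv_modes(12.0, 0.0, self.AREA, n_modes=5,
                                n_frames=600, seed=0)
        with pytest.raises(ValueError):
            guv_bending_modulus(amps, q, self.AREA)
        amps, q = gen_guv_modes(12.0, 0.0, self.AREA, n_modes=12,
                                n_frames=100, seed=0)
        with pytest.raises(ValueError):
            guv_bending_modulus(amps, q, self.AREA)
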