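"""QUS spectral analysis: window grid, spectra, attenuation, BSC
normalization, linear and form-factor parametrization, full maps."""

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from qusrad.config import FormFactorConfig, SpectralConfig
from qusrad.phantom import RFFrame, ROISet, analytic_bsc
from qusrad.spectral import (
    SpectrumEstimate,
    average_power_spectrum,
    build_parametric_maps,
    correct_attenuation,
    estimate_attenuation_spectral_difference,
    fit_gaussian_form_factor,
    fit_linear_spectral,
    normalize_to_bsc,
    sliding_window_grid,
)

from conftest import homogeneous_frame


def _flat_frame(acq, seed=0):
    rng = np.random.default_rng(seed)
    return RFFrame(
        rng.standard_normal((acq.n_axial, acq.n_lateral)),
        fs_axial_mhz=acq.fs_axial_mhz,
        lateral_pitch_mm=acq.lateral_pitch_mm,
    )


class TestWindowGrid:
    def test_lateral_step_is_map_spacing(self, acq, spectral_cfg, square_roi):
        """2 mm window at 94% overlap -> 0.12 mm lateral step."""
        assert np.isclose(spectral_cfg.step_mm, 0.12)
        grid = sliding_window_grid(square_roi, _flat_frame(acq), spectral_cfg)
        assert np.allclose(np.diff(grid.lat_center_mm), 0.12)
        # axial step quantized to the sample pitch: within one pitch of 0.12
        ax_step = np.diff(grid.ax_center_mm)[0]
        pitch = 1540.0 / (2 * 40e6) * 1e3
        assert abs(ax_step - 0.12) <= pitch

    def test_zero_overlap_disjoint_windows(self, acq, square_roi):
        cfg = SpectralConfig(overlap_fraction=0.0)
        grid = sliding_window_grid(square_roi, _flat_frame(acq), cfg)
        assert np.all(np.diff(grid.lat_start) >= grid.window_lines)
        assert np.all(np.diff(grid.ax_start) >= grid.window_samples)

    def test_center_count_matches_brute_force(self, acq, spectral_cfg, square_roi):
        frame = _flat_frame(acq)
        grid = sliding_window_grid(square_roi, frame, spectral_cfg)
        xx, yy = np.meshgrid(grid.lat_center_mm, grid.ax_center_mm)
        brute = shapely.contains_xy(
            square_roi.core, xx.ravel(), yy.ravel()
        ) | shapely.contains_xy(square_roi.margin, xx.ravel(), yy.ravel())
        assert grid.any_mask.sum() == brute.sum()

    def test_window_tags_match_region(self, acq, spectral_cfg, square_roi):
        grid = sliding_window_grid(square_roi, _flat_frame(acq), spectral_cfg)
        assert not np.any(grid.core & grid.margin)
        assert grid.core.sum() > 0 and grid.margin.sum() > 0

    def test_too_small_roi_errors(self, acq, spectral_cfg):
        tiny = ROISet(core=box(9.0, 9.0, 9.4, 9.4))
        # center the margin ring away from the window grid entirely
        frame = RFFrame(
            np.zeros((120, 20)),
            fs_axial_mhz=40.0,
            lateral_pitch_mm=0.12,
        )
        with pytest.raises(ValueError):
            sliding_window_grid(ROISet(core=box(50, 50, 51, 51)), frame, spectral_cfg)


class TestAveragePowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self, spectral_cfg):
        fs = 40.0
        t = np.arange(512) / fs
        block = np.sin(2 * np.pi * 5.0 * t)[:, None] * np.ones((1, 4))
        spec = average_power_spectrum(block, spectral_cfg, fs)
        assert abs(spec.freq_mhz[np.argmax(spec.power_db)] - 5.0) < 0.1

    def test_white_noise_flat_inband(self, spectral_cfg):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((256, 400))
        spec = average_power_spectrum(block, spectral_cfg, 40.0)
        assert np.ptp(spec.power_db) < 1.0

    def test_amplitude_doubling_adds_6db(self, spectral_cfg):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((128, 8))
        s1 = average_power_spectrum(block, spectral_cfg, 40.0)
        s2 = average_power_spectrum(2 * block, spectral_cfg, 40.0)
        np.testing.assert_allclose(
            s2.power_db - s1.power_db, 20 * np.log10(2), atol=1e-9
        )

    def test_all_zero_block_rejected(self, spectral_cfg):
        with pytest.raises(ValueError, match="zero"):
            average_power_spectrum(np.zeros((64, 4)), spectral_cfg, 40.0)


class TestAttenuationEstimation:
    def test_closed_form_decay_recovered_exactly(self):
        """dB spectra decaying exactly as 2*alpha*f*d -> exact recovery."""
        alpha = 0.65
        freq = np.linspace(3, 8, 20)
        depths = np.linspace(1.0, 3.0, 15)  # cm
        power = np.array([-2 * alpha * f * depths for f in freq]).T
        est = estimate_attenuation_spectral_difference(freq, power, depths)
        assert np.isclose(est.alpha_db_cm_mhz, alpha, atol=1e-10)
        assert est.fit_r2 > 1 - 1e-12

    def test_null_recovery_on_attenuation_free_phantom(
        self, acq, spectral_cfg, square_roi
    ):
        frame = homogeneous_frame(acq, alpha=0.0, seed=61)
        import qusrad.spectral as sp

        grid = sliding_window_grid(square_roi, frame, spectral_cfg)
        freq, pdb = sp._grid_power_db(frame, grid, spectral_cfg)
        rows, cols = np.nonzero(grid.any_mask)
        est = estimate_attenuation_spectral_difference(
            freq, pdb[rows, cols], grid.ax_center_mm[rows] * 0.1
        )
        assert abs(est.alpha_db_cm_mhz) < 0.05

    def test_known_attenuation_recovered(self, acq, spectral_cfg, square_roi):
        frame = homogeneous_frame(acq, alpha=0.7, seed=62)
        import qusrad.spectral as sp

        grid = sliding_window_grid(square_roi, frame, spectral_cfg)
        freq, pdb = sp._grid_power_db(frame, grid, spectral_cfg)
        rows, cols = np.nonzero(grid.any_mask)
        est = estimate_attenuation_spectral_difference(
            freq, pdb[rows, cols], grid.ax_center_mm[rows] * 0.1
        )
        assert abs(est.alpha_db_cm_mhz - 0.7) < 0.15

    def test_single_depth_rejected(self):
        freq = np.linspace(3, 8, 10)
        with pytest.raises(ValueError, match="depth"):
            estimate_attenuation_spectral_difference(
                freq, np.zeros((3, 10)), np.full(3, 2.0)
            )


class TestAttenuationCorrection:
    def test_zero_thickness_identity(self):
        spec = SpectrumEstimate(np.linspace(3, 8, 6), np.zeros(6))
        out = correct_attenuation(spec, [(0.8, 0.0)])
        np.testing.assert_array_equal(out.power_db, spec.power_db)

    def test_gain_arithmetic(self):
        freq = np.array([5.0, 8.0])
        spec = SpectrumEstimate(freq, np.zeros(2))
        out = correct_attenuation(spec, [(1.0, 1.0)])
        np.testing.assert_allclose(out.power_db, [10.0, 16.0])

    def test_round_trip_with_estimator(self):
        """Correcting with alpha then re-estimating gives residual ~ 0."""
        alpha = 0.5
        freq = np.linspace(3, 8, 12)
        depths = np.linspace(1.0, 2.5, 8)
        power = np.array([-2 * alpha * f * depths for f in freq]).T
        corrected = np.stack(
            [
                correct_attenuation(
                    SpectrumEstimate(freq, p), [(alpha, d)]
                ).power_db
                for p, d in zip(power, depths)
            ]
        )
        est = estimate_attenuation_spectral_difference(freq, corrected, depths)
        assert abs(est.alpha_db_cm_mhz) < 1e-10


class TestBSCNormalization:
    def test_sample_equals_reference_identity(self, reference):
        spec = SpectrumEstimate(reference.freq_mhz, reference.power_db)
        np.testing.assert_allclose(normalize_to_bsc(spec, reference), reference.bsc)

    def test_plus_3db_scales_linearly(self, reference):
        spec = SpectrumEstimate(reference.freq_mhz, reference.power_db + 3.0)
        np.testing.assert_allclose(
            normalize_to_bsc(spec, reference), 10 ** 0.3 * reference.bsc
        )

    def test_band_mismatch_rejected(self, reference):
        spec = SpectrumEstimate(reference.freq_mhz[:-1], reference.power_db[:-1])
        with pytest.raises(ValueError, match="grid"):
            normalize_to_bsc(spec, reference)

    def test_simulated_phantom_bsc_matches_analytic(
        self, acq, spectral_cfg, reference, square_roi
    ):
        """Recovered BSC within 1.5 dB RMS of the form-factor curve."""
        import qusrad.spectral as sp

        frame = homogeneous_frame(acq, asd_um=80.0, aac_db=3.0, seed=21)
        grid = sliding_window_grid(square_roi, frame, spectral_cfg)
        freq, pdb = sp._grid_power_db(frame, grid, spectral_cfg)
        lin = (10 ** (pdb[grid.any_mask] / 10)).mean(axis=0)
        spec = SpectrumEstimate(freq, 10 * np.log10(lin))
        bsc = normalize_to_bsc(spec, reference)
        truth = analytic_bsc(freq, 80.0, 3.0)
        rms_db = np.sqrt(np.mean((10 * np.log10(bsc / truth)) ** 2))
        assert rms_db < 1.5


class TestLinearSpectralFit:
    def test_exact_line(self, spectral_cfg):
        freq = np.linspace(3, 8, 11)
        spec = SpectrumEstimate(freq, 2 * freq + 3)
        mbf, ss, si = fit_linear_spectral(spec, spectral_cfg)
        assert np.isclose(ss, 2) and np.isclose(si, 3)
        assert np.isclose(mbf, 2 * 5.5 + 3)

    def test_flat_spectrum(self, spectral_cfg):
        freq = np.linspace(3, 8, 11)
        mbf, ss, si = fit_linear_spectral(
            SpectrumEstimate(freq, np.full(11, -7.0)), spectral_cfg
        )
        assert np.isclose(ss, 0) and np.isclose(si, -7) and np.isclose(mbf, -7)

    def test_noisy_line_unbiased_and_identity_exact(self, spectral_cfg):
        rng = np.random.default_rng(3)
        freq = np.linspace(3, 8, 17)
        slopes, intercepts = [], []
        for _ in range(200):
            spec = SpectrumEstimate(
                freq, 1.5 * freq - 20 + rng.normal(0, 1, 17)
            )
            mbf, ss, si = fit_linear_spectral(spec, spectral_cfg)
            assert mbf == ss * spectral_cfg.f_mid_mhz + si  # exact identity
            slopes.append(ss)
            intercepts.append(si)
        assert abs(np.mean(slopes) - 1.5) < 2 * np.std(slopes) / np.sqrt(200)
        assert abs(np.mean(intercepts) + 20) < 2 * np.std(intercepts) / np.sqrt(200)


class TestFormFactorFit:
    def test_exact_inversion_of_own_model(self, ff_cfg):
        freq = np.linspace(3, 8, 20)
        bsc = analytic_bsc(freq, asd_um=50.0, aac_db=2.0)
        asd, aac, flagged = fit_gaussian_form_factor(bsc, freq, ff_cfg)
        assert not flagged
        assert np.isclose(asd, 50.0, rtol=1e-10)
        assert np.isclose(aac, 2.0, atol=1e-10)

    def test_pure_f4_flags_zero_diameter(self, ff_cfg):
        freq = np.linspace(3, 8, 20)
        asd, aac, flagged = fit_gaussian_form_factor(freq**4, freq, ff_cfg)
        assert flagged and asd == 0.0
        assert np.isclose(aac, 0.0, atol=1e-10)

    def test_noisy_fit_agrees_with_grid_search_oracle(self, ff_cfg):
        """Linearized fit vs brute-force dB-RMS grid search."""
        rng = np.random.default_rng(8)
        freq = np.linspace(3, 8, 20)
        truth_asd = 80.0
        bsc = analytic_bsc(freq, truth_asd, 0.0) * 10 ** (
            rng.uniform(-1, 1, 20) / 10
        )
        asd_fit, aac_fit, _ = fit_gaussian_form_factor(bsc, freq, ff_cfg)
        grid_asd = np.arange(20, 160, 0.5)
        grid_aac = np.arange(-6, 6, 0.1)
        best = (np.inf, None, None)
        meas_db = 10 * np.log10(bsc)
        for a in grid_asd:
            model0 = 10 * np.log10(analytic_bsc(freq, a, 0.0))
            for c in grid_aac:
                rms = np.sqrt(np.mean((meas_db - model0 - c) ** 2))
                if rms < best[0]:
                    best = (rms, a, c)
        _, asd_oracle, aac_oracle = best
        assert abs(asd_fit - asd_oracle) / asd_oracle < 0.10
        assert abs(aac_fit - aac_oracle) < 1.0

    def test_nonpositive_bsc_rejected(self, ff_cfg):
        freq = np.linspace(3, 8, 5)
        with pytest.raises(ValueError):
            fit_gaussian_form_factor(np.array([1, 2, 0, 4, 5.0]), freq, ff_cfg)


class TestParametricMaps:
    def test_homogeneous_phantom_low_spatial_variation(self, homogeneous_maps):
        """Homogeneous phantom: low spatial variation inside the core.

        Channels on a dB scale can sit near zero, so each channel's
        spatial standard deviation is compared against its display
        dynamic range; ASD, a positive-scale quantity, additionally gets
        a plain coefficient-of-variation bound.
        """
        from qusrad.spectral import CHANNEL_DISPLAY_RANGE

        m = homogeneous_maps
        for ch in ("MBF", "SS", "SI", "ASD", "AAC"):
            vals = m.channel(ch)[m.core_mask]
            assert np.std(vals) / CHANNEL_DISPLAY_RANGE[ch] < 0.15, ch
        asd = m.channel("ASD")[m.core_mask]
        assert np.std(asd) / np.mean(asd) < 0.15

    def test_mbf_identity_every_window(self, homogeneous_maps, spectral_cfg):
        m = homogeneous_maps
        sel = m.valid_mask
        lhs = m.channel("MBF")[sel]
        rhs = m.channel("SS")[sel] * spectral_cfg.f_mid_mhz + m.channel("SI")[sel]
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-10)

    def test_grid_lateral_spacing_contract(self, homogeneous_maps):
        assert np.isclose(homogeneous_maps.grid_spacing_mm[1], 0.12)

    def test_invalid_outside_roi(self, homogeneous_maps):
        m = homogeneous_maps
        outside = ~m.valid_mask
        assert np.all(np.isnan(m.channel("ASD")[outside]))

    def test_two_region_phantom_contrast_direction(
        self, acq, spectral_cfg, ff_cfg, reference
    ):
        """Margin with larger scatterers -> larger recovered ASD there."""
        from qusrad.phantom import (
            PhantomSpec,
            RegionAcoustics,
            ROISet,
            generate_scatterer_field,
            synthesize_rf_frame,
        )

        roi = ROISet(core=box(7, 7, 13, 13))
        spec = PhantomSpec(
            regions={
                "core": RegionAcoustics(30.0, 0.0),  # ASD 60
                "margin": RegionAcoustics(55.0, 0.0),  # ASD 110
                "background": RegionAcoustics(30.0, 0.0),
            },
            seed=42,
        )
        field = generate_scatterer_field(spec, roi, (20.0, 20.0), seed=42)
        frame = synthesize_rf_frame(field, spec, acq, seed=43)
        maps = build_parametric_maps(frame, roi, reference, spectral_cfg, ff_cfg)
        asd = maps.channel("ASD")
        assert (
            np.nanmedian(asd[maps.margin_mask])
            > np.nanmedian(asd[maps.core_mask]) + 20
        )
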