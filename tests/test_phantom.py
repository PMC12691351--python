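"""Synthetic RF phantom generator: determinism, speckle statistics,
concentration scaling and cohort layout."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import hilbert
from shapely.geometry import box

from qusrad.phantom import (
    AcquisitionGeometry,
    ClinicalRecord,
    PhantomSpec,
    RegionAcoustics,
    ROISet,
    generate_cohort,
    generate_reference_frames,
    generate_scatterer_field,
    load_cohort,
    save_cohort,
    synthesize_rf_frame,
    analytic_bsc,
)

from conftest import homogeneous_frame


def _spec(density=20.0, het=0.0, seed=7, aac=0.0):
    return PhantomSpec(
        regions={
            "background": RegionAcoustics(40.0, aac),
            "core": RegionAcoustics(40.0, aac),
            "margin": RegionAcoustics(40.0, aac),
        },
        scatterer_density_mm2=density,
        margin_heterogeneity=het,
        seed=seed,
    )


class TestScattererField:
    def test_density_sets_expected_count(self):
        field = generate_scatterer_field(_spec(20.0), None, (10.0, 10.0), seed=7)
        # Poisson(2000): +/- 5 sigma
        assert abs(len(field) - 2000) < 5 * np.sqrt(2000)

    def test_same_seed_identical_different_seed_not(self):
        a = generate_scatterer_field(_spec(), None, (10.0, 10.0), seed=3)
        b = generate_scatterer_field(_spec(), None, (10.0, 10.0), seed=3)
        c = generate_scatterer_field(_spec(), None, (10.0, 10.0), seed=4)
        np.testing.assert_array_equal(a.x_mm, b.x_mm)
        np.testing.assert_array_equal(a.amplitude, b.amplitude)
        assert len(a) != len(c) or not np.allclose(a.x_mm, c.x_mm)

    @staticmethod
    def _margin_cell_variance_cv(het: float) -> float:
        """CV of amplitude variance over 1.5 mm margin cells."""
        roi = ROISet(core=box(8, 8, 12, 12))
        spec = _spec(density=600.0, het=het)
        field = generate_scatterer_field(spec, roi, (20.0, 20.0), seed=5)
        m = field.region == "margin"
        x, z, amp = field.x_mm[m], field.z_mm[m], field.amplitude[m]
        variances = []
        for x0 in np.arange(3, 17, 1.5):
            for z0 in np.arange(3, 17, 1.5):
                sel = (x >= x0) & (x < x0 + 1.5) & (z >= z0) & (z < z0 + 1.5)
                if sel.sum() > 100:
                    variances.append(np.var(amp[sel]))
        return float(np.std(variances) / np.mean(variances))

    def test_zero_heterogeneity_margin_variance_uniform(self):
        assert self._margin_cell_variance_cv(0.0) < 0.10

    def test_heterogeneity_modulates_margin_variance(self):
        assert self._margin_cell_variance_cv(1.5) > 0.3

    def test_empty_region_raises(self):
        tiny = ROISet(core=box(8, 8, 8.4, 8.4))
        with pytest.raises(ValueError, match="core"):
            generate_scatterer_field(_spec(density=0.5), tiny, (20.0, 20.0), seed=1)


class TestRFSynthesis:
    def test_same_seed_bit_identical(self, acq):
        spec = _spec()
        field = generate_scatterer_field(spec, None, (20.0, 20.0), seed=9)
        f1 = synthesize_rf_frame(field, spec, acq, seed=2)
        f2 = synthesize_rf_frame(field, spec, acq, seed=2)
        np.testing.assert_array_equal(f1.samples, f2.samples)

    def test_no_depth_decay_without_attenuation(self, acq):
        frame = homogeneous_frame(acq, asd_um=10.0, alpha=0.0, seed=31)
        n = frame.n_axial
        shallow = frame.samples[n // 8 : n // 4]
        deep = frame.samples[3 * n // 4 : 7 * n // 8]
        p_sh = np.mean(shallow**2)
        p_dp = np.mean(deep**2)
        assert abs(10 * np.log10(p_dp / p_sh)) < 1.0

    def test_doubling_concentration_raises_spectrum_3db(self, acq):
        """+3 dB concentration -> +3 dB ensemble power at in-band freqs."""
        powers = {0.0: [], 3.0: []}
        for aac in powers:
            for rep in range(6):
                frame = homogeneous_frame(
                    acq, asd_um=10.0, aac_db=aac, seed=100 + rep
                )
                f = np.fft.rfftfreq(frame.n_axial, 1 / frame.fs_axial_mhz)
                p = np.mean(
                    np.abs(np.fft.rfft(frame.samples, axis=0)) ** 2, axis=1
                )
                band = (f >= 4) & (f <= 7)
                powers[aac].append(p[band])
        ratio = 10 * np.log10(
            np.mean(powers[3.0], axis=0) / np.mean(powers[0.0], axis=0)
        )
        assert np.all(np.abs(ratio - 3.0) < 0.5)

    def test_envelope_rayleigh_in_homogeneous_region(self, acq):
        frame = homogeneous_frame(acq, seed=55)
        env = np.abs(hilbert(frame.samples[100:900, 20:150], axis=0))
        sample = env.ravel()[::997]
        stat = sps.kstest(
            sample, "rayleigh", args=(0, np.sqrt(np.mean(sample**2) / 2))
        )
        assert stat.pvalue > 0.01

    def test_band_above_nyquist_rejected(self):
        acq = AcquisitionGeometry(
            depth_mm=10, width_mm=5, fs_axial_mhz=15.0, band_mhz=(3.0, 8.0)
        )
        spec = _spec()
        field = generate_scatterer_field(spec, None, (10.0, 5.0), seed=1)
        with pytest.raises(ValueError, match="[Nn]yquist"):
            synthesize_rf_frame(field, spec, acq, seed=1)


class TestReferencePhantom:
    def test_frame_count_and_distinct_speckle(self, acq):
        frames, meta = generate_reference_frames(acq, n_frames=4, seed=8)
        assert len(frames) == 4
        assert meta["alpha_db_cm_mhz"] == 0.0
        assert not np.allclose(frames[0].samples, frames[1].samples)

    def test_analytic_bsc_matches_formula_by_hand(self):
        f = 6.5
        asd, aac, b_ff, c = 50.0, 2.0, 0.827, 1540.0
        k = 2 * np.pi * f * 1e6 / c
        a = asd / 2 * 1e-6
        expected = 10 ** (aac / 10) * f**4 * np.exp(-2 * b_ff * k**2 * a**2)
        assert np.isclose(analytic_bsc(np.array([f]), asd, aac)[0], expected)


class TestCohort:
    def test_study_cohort_layout(self, acq):
        patients = generate_cohort(
            n_low=3, n_high=5, frames_per_patient=2, acq=acq, seed=1
        )
        assert len(patients) == 8
        labels = [p.clinical.label for p in patients]
        assert labels.count(0) == 3 and labels.count(1) == 5
        assert sum(len(p.frames) for p in patients) == 16
        for p in patients:
            assert (p.clinical.odxrs > 15) == bool(p.clinical.label)
            for roi in p.rois:
                assert roi.core.is_valid and not roi.margin.is_empty
                assert roi.margin.intersection(roi.core).area < 1e-9

    def test_minimal_cohort(self, acq):
        patients = generate_cohort(1, 1, 1, acq=acq, seed=2)
        assert len(patients) == 2
        assert all(len(p.frames) == 1 for p in patients)

    def test_cohort_deterministic(self, acq):
        a = generate_cohort(1, 2, 1, acq=acq, seed=9)
        b = generate_cohort(1, 2, 1, acq=acq, seed=9)
        for pa, pb in zip(a, b):
            assert pa.clinical == pb.clinical
            np.testing.assert_array_equal(
                pa.frames[0].samples, pb.frames[0].samples
            )

    def test_save_load_roundtrip(self, acq, tmp_path):
        patients = generate_cohort(1, 1, 1, acq=acq, seed=4)
        save_cohort(patients, tmp_path)
        loaded = load_cohort(tmp_path)
        assert len(loaded) == 2
        np.testing.assert_allclose(
            loaded[0].frames[0].samples, patients[0].frames[0].samples
        )
        assert loaded[0].clinical == patients[0].clinical


class TestClinicalRecord:
    def test_label_follows_threshold(self):
        assert ClinicalRecord("p", 15).label == 0
        assert ClinicalRecord("p", 16).label == 1

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValueError):
            ClinicalRecord("p", 20, label=0)
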