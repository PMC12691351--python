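"""Feature engineering: preprocessing, wavelets, discretization,
first-order and shape features, the 4659-feature identity, aggregation."""

import numpy as np
import pytest
import shapely.affinity
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

import oracles
from qusrad.config import RadiomicsConfig
from qusrad.features import (
    FIRSTORDER_NAMES,
    SHAPE2D_NAMES,
    FeatureVector,
    aggregate_patient,
    discretize,
    expected_feature_count,
    extract_frame_features,
    firstorder_features,
    inverse_wavelet_subbands,
    preprocess_map,
    shape2d_features,
    wavelet_subbands,
)


class TestPreprocess:
    def test_zscore_scaling_definition(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 2, (40, 40))
        mask = np.ones((40, 40), dtype=bool)
        cfg = RadiomicsConfig()
        out, m = preprocess_map(img, mask, cfg, (0.12, 0.12))
        assert abs(np.mean(out[m])) < 1.0
        # the +/-3 sigma trim shaves ~1.5% off the post-removal sd
        assert abs(np.std(out[m]) - 100) < 3.0

    def test_outlier_pixel_removed(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 1, (30, 30))
        img[10, 10] = 10 * np.std(img) + np.mean(img)
        mask = np.ones((30, 30), dtype=bool)
        out, m = preprocess_map(img, mask, RadiomicsConfig(), (0.12, 0.12))
        assert not m[10, 10]
        assert m.sum() >= 30 * 30 - 5

    def test_constant_map_flagged_zero(self):
        img = np.full((20, 20), 3.0)
        mask = np.ones((20, 20), dtype=bool)
        out, m = preprocess_map(img, mask, RadiomicsConfig(), (0.12, 0.12))
        assert np.all(out == 0)

    def test_resampling_ramp_matches_analytic(self):
        """Bilinear ramp resampled 0.2 -> 0.12 mm: values follow the ramp."""
        ny, nx = 40, 50
        img = np.add.outer(np.arange(ny) * 0.2, np.arange(nx) * 0.2 * 2)
        mask = np.ones((ny, nx), dtype=bool)
        out, m = preprocess_map(img, mask, RadiomicsConfig(), (0.2, 0.2))
        # reconstruct the expected z-scored ramp analytically on the new grid
        mu, sd = img.mean(), img.std()
        yy = np.arange(out.shape[0]) * 0.12
        xx = np.arange(out.shape[1]) * 0.12
        expected = (np.add.outer(yy, 2 * xx) - mu) / sd * 100
        # B-spline edge effects: compare away from the borders
        core = (slice(4, -4), slice(4, -4))
        err = np.abs(out[core] - expected[core]) / np.ptp(expected)
        assert err.max() < 0.01


class TestWavelets:
    def test_constant_image_vanishes_in_detail_bands(self):
        subs = wavelet_subbands(np.full((32, 32), 7.0))
        for k in ("LH", "HL", "HH"):
            assert np.abs(subs[k]).max() < 1e-12
        assert np.allclose(subs["LL"], 14.0)  # gain 2 (sqrt(2) per axis)

    def test_step_edge_energy_lands_in_matching_subband(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0  # vertical edge: high-pass across columns
        subs = wavelet_subbands(img)
        e = {k: float(np.sum(subs[k] ** 2)) for k in ("LH", "HL", "HH")}
        assert e["LH"] > 10 * e["HL"] and e["LH"] > 10 * e["HH"]

    def test_reconstruction_interior_machine_precision(self):
        rng = np.random.default_rng(2)
        img = rng.standard_normal((48, 64))
        rec = inverse_wavelet_subbands(wavelet_subbands(img))
        interior = (slice(12, -12), slice(12, -12))
        assert np.abs(rec[interior] - img[interior]).max() < 1e-10

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            wavelet_subbands(np.zeros((4, 4)))


class TestDiscretize:
    def test_floor_arithmetic(self):
        img = np.array([[0.0, 14.9], [15.0, 45.0]])
        mask = np.ones((2, 2), dtype=bool)
        levels, n = discretize(img, mask, 15.0)
        np.testing.assert_array_equal(levels, [[1, 1], [2, 4]])
        assert n == 4

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        vals=st.lists(st.floats(-1e5, 1e5), min_size=2, max_size=40),
        bw=st.floats(0.5, 100),
    )
    def test_level_floor_property(self, vals, bw):
        """Every level matches the floor definition; the minimum maps to 1."""
        img = np.array(vals)[None, :]
        mask = np.ones_like(img, dtype=bool)
        levels, n = discretize(img, mask, bw)
        lo = img.min()
        expected = np.floor((img - lo) / bw).astype(int) + 1
        np.testing.assert_array_equal(levels, expected)
        assert levels.min() == 1 and n == levels.max()

    def test_constant_region_single_level(self):
        levels, n = discretize(np.full((3, 3), 8.0), np.ones((3, 3), bool), 15.0)
        assert n == 1 and np.all(levels == 1)

    def test_uniform_occupancy(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 150, (100, 100))
        levels, n = discretize(img, np.ones((100, 100), bool), 15.0)
        assert n == 10
        assert len(np.unique(levels)) == 10


class TestFirstOrder:
    def test_hand_arithmetic(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), dtype=bool)
        f = firstorder_features(img, mask)
        assert f["Mean"] == 2.5
        assert f["Variance"] == 1.25  # population variance
        assert f["Range"] == 3.0
        assert f["Energy"] == 30.0

    def test_constant_region_conventions(self):
        img = np.full((3, 3), 4.0)
        f = firstorder_features(img, np.ones((3, 3), bool))
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 3.0
        assert f["Uniformity"] == 1.0

    def test_gaussian_sample_moments(self):
        rng = np.random.default_rng(4)
        img = rng.standard_normal((25, 40))
        f = firstorder_features(img, np.ones((25, 40), bool))
        assert abs(f["Skewness"]) < 0.25
        assert abs(f["Kurtosis"] - 3.0) < 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.normal(50, 20, (16, 16))
        mask = rng.random((16, 16)) < 0.8
        mask[0, 0] = True
        ours = firstorder_features(img, mask, bin_width=15.0, pixel_area_mm2=0.0144)
        ref = oracles.naive_firstorder(img[mask], 15.0, 0.0144)
        for k in FIRSTORDER_NAMES:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10), k


class TestShape2D:
    def test_circle_analytics(self):
        circle = Point(0, 0).buffer(10.0, quad_segs=256)
        f = shape2d_features(circle, raster_spacing_mm=0.05)
        assert f["MeshSurface"] == pytest.approx(np.pi * 100, rel=0.02)
        assert f["Sphericity"] == pytest.approx(1.0, rel=0.02)
        assert f["MaximumDiameter"] == pytest.approx(20.0, rel=0.02)

    def test_ellipse_elongation(self):
        ellipse = shapely.affinity.scale(Point(0, 0).buffer(1.0, quad_segs=128), 10, 5)
        f = shape2d_features(ellipse, raster_spacing_mm=0.05)
        assert f["Elongation"] == pytest.approx(0.5, rel=0.05)
        assert f["MajorAxisLength"] == pytest.approx(20.0, rel=0.05)

    def test_square_less_spherical_than_circle(self):
        square = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        circle = Point(0, 0).buffer(np.sqrt(100 / np.pi), quad_segs=128)
        fs = shape2d_features(square)
        fc = shape2d_features(circle)
        assert fs["Sphericity"] < fc["Sphericity"]
        assert fs["MeshSurface"] == pytest.approx(fc["MeshSurface"], rel=0.01)


class TestExtraction:
    def test_full_configuration_yields_4659(self, homogeneous_maps, square_roi):
        cfg = RadiomicsConfig()
        assert expected_feature_count(cfg) == 4659
        fv = extract_frame_features(homogeneous_maps, square_roi, cfg)
        assert len(fv.names) == 4659
        assert len(set(fv.names)) == 4659
        assert not np.any(np.isnan(fv.values))

    def test_restricted_configuration_arithmetic(self, homogeneous_maps, square_roi):
        cfg = RadiomicsConfig(
            channels=("MBF",), regions=("core",), image_types=("original",)
        )
        assert expected_feature_count(cfg) == 18 + 75 + 9

    def test_feature_names_structured(self, homogeneous_maps, square_roi):
        fv = extract_frame_features(homogeneous_maps, square_roi, RadiomicsConfig())
        assert "original_glcm_Correlation_margin_AAC" in fv.names
        assert "wavelet-LL_firstorder_Mean_core_MBF" in fv.names
        assert "original_shape2D_Sphericity_core_all" in fv.names

    def test_two_realizations_similar_features(
        self, acq, spectral_cfg, ff_cfg, reference, square_roi
    ):
        """Two frames of the same phantom: feature vectors highly correlated."""
        from conftest import homogeneous_frame
        from qusrad.spectral import build_parametric_maps

        cfg = RadiomicsConfig()
        vecs = []
        for seed in (201, 301):
            frame = homogeneous_frame(acq, seed=seed)
            maps = build_parametric_maps(
                frame, square_roi, reference, spectral_cfg, ff_cfg
            )
            vecs.append(extract_frame_features(maps, square_roi, cfg).values)
        a, b = vecs
        scale = np.maximum(np.abs(a) + np.abs(b), 1e-12)
        # z-scale across features and correlate
        r = np.corrcoef((a - a.mean()) / a.std(), (b - b.mean()) / b.std())[0, 1]
        assert r > 0.95


class TestAggregation:
    def _fv(self, values, weight):
        return FeatureVector(
            names=[f"f{i}" for i in range(len(values))],
            values=np.asarray(values, dtype=float),
            roi_weight=weight,
        )

    def test_single_frame_identity(self):
        fv = self._fv([1.0, 2.0], 10)
        out = aggregate_patient([fv])
        np.testing.assert_array_equal(out.values, fv.values)

    def test_equal_weights_mean(self):
        out = aggregate_patient([self._fv([1.0], 5), self._fv([3.0], 5)])
        assert out.values[0] == 2.0

    def test_weighted_mean_hand_value(self):
        out = aggregate_patient([self._fv([0.0], 1), self._fv([4.0], 3)])
        assert out.values[0] == 3.0

    def test_convex_combination_property(self):
        rng = np.random.default_rng(6)
        frames = [self._fv(rng.normal(size=7), w) for w in (1, 2.5, 4)]
        out = aggregate_patient(frames)
        stack = np.stack([f.values for f in frames])
        assert np.all(out.values >= stack.min(axis=0) - 1e-12)
        assert np.all(out.values <= stack.max(axis=0) + 1e-12)

    def test_name_mismatch_rejected(self):
        a = self._fv([1.0], 1)
        b = FeatureVector(names=["other"], values=np.array([2.0]), roi_weight=1)
        with pytest.raises(ValueError, match="name"):
            aggregate_patient([a, b])
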