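import numpy as np
import pytest

from hemoscat import estimator as est
from hemoscat import trainer
from hemoscat.tissue_optics import ISOSBESTIC_WAVELENGTHS


def stack_from_reflectance(R, white=1.0, **kwargs):
    """Build a ReflectanceStack whose normalized reflectance equals R."""
    R = np.asarray(R, dtype=float)
    wr = np.full_like(R, white)
    return est.ReflectanceStack(images=R * white, white_reference=wr, **kwargs)


@pytest.fixture
def toy_model():
    """Regression model with hand-set coefficients for arithmetic checks."""
    return trainer.RegressionModel(
        alpha=np.array([1.0, 0.5, 0.0, 0.0, 0.0]),
        beta=np.array([0.1, 0.0, 0.0, 0.0, 0.2]),
        training_r2_b=1.0,
        training_r2_cth=1.0,
        grid_hash="toy",
    )


class TestNormalization:
    def test_sample_equal_to_reference_gives_unity(self):
        stack = stack_from_reflectance(np.ones((4, 5, 5)), white=0.8)
        R, valid = est.normalize_reflectance(stack)
        np.testing.assert_allclose(R, 1.0)
        assert valid.all()

    def test_half_intensity_gives_half_reflectance(self):
        stack = stack_from_reflectance(np.full((4, 3, 3), 0.5), white=200.0)
        R, _ = est.normalize_reflectance(stack)
        np.testing.assert_allclose(R, 0.5)

    def test_zero_reference_marks_invalid_not_infinite(self):
        imgs = np.full((4, 2, 2), 0.5)
        wr = np.ones((4, 2, 2))
        wr[:, 0, 0] = 0.0
        stack = est.ReflectanceStack(images=imgs, white_reference=wr)
        R, valid = est.normalize_reflectance(stack)
        assert not valid[0, 0] and valid[1, 1]
        assert np.isnan(R[:, 0, 0]).all()
        assert np.isfinite(R[:, 1, 1]).all()

    def test_reflectance_above_one_is_invalid(self):
        imgs = np.full((4, 2, 2), 1.5)
        stack = est.ReflectanceStack(images=imgs, white_reference=np.ones((4, 2, 2)))
        _, valid = est.normalize_reflectance(stack)
        assert not valid.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            est.ReflectanceStack(
                images=np.ones((4, 4, 4)), white_reference=np.ones((4, 3, 3))
            )

    def test_wrong_band_count_rejected(self):
        with pytest.raises(ValueError):
            est.ReflectanceStack(images=np.ones((3, 4, 4)), white_reference=np.ones(3))


class TestAbsorbance:
    @pytest.mark.parametrize("R,A", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decade_rule(self, R, A):
        assert est.absorbance(np.array([R]))[0] == pytest.approx(A)

    def test_monotone_decreasing_in_reflectance(self):
        R = np.linspace(0.05, 1.0, 20)
        A = est.absorbance(R)
        assert np.all(np.diff(A) < 0)

    def test_nonpositive_reflectance_rejected(self):
        with pytest.raises(ValueError):
            est.absorbance(np.array([0.5, -0.1]))


class TestEstimateMaps:
    def test_identical_pixels_identical_estimates(self, toy_model):
        R = np.full((4, 4, 4), 0.5)
        maps = est.estimate_maps(stack_from_reflectance(R), toy_model)
        assert np.unique(maps.b_map).size == 1
        assert np.unique(maps.cth_map).size == 1

    def test_linear_formula_applied_per_pixel(self, toy_model):
        R = np.full((4, 1, 1), 0.1)  # A = 1 in every band
        maps = est.estimate_maps(stack_from_reflectance(R), toy_model)
        assert maps.b_map[0, 0] == pytest.approx(1.0 + 0.5)
        assert maps.cth_map[0, 0] == pytest.approx(0.1 + 0.2)

    def test_all_invalid_stack_is_fully_masked(self, toy_model):
        imgs = np.ones((4, 3, 3))
        wr = np.zeros((4, 3, 3))
        maps = est.estimate_maps(
            est.ReflectanceStack(images=imgs, white_reference=wr), toy_model
        )
        assert not maps.valid_mask.any()
        assert np.isnan(maps.cth_map).all()

    def test_out_of_range_estimates_flagged_not_clipped(self, toy_model):
        # A = 8 per band -> b = 5 (outside [1, 4]); value kept, flag cleared
        R = np.full((4, 2, 2), 1e-8)
        maps = est.estimate_maps(stack_from_reflectance(R), toy_model)
        assert not maps.valid_mask.any()
        assert maps.b_map[0, 0] == pytest.approx(5.0)

    def test_grid_hash_mismatch_rejected(self, toy_model):
        stack = stack_from_reflectance(np.full((4, 2, 2), 0.5), grid_hash="other")
        with pytest.raises(ValueError, match="grid_hash"):
            est.estimate_maps(stack, toy_model)

    def test_consistency_with_training_predictions(self, small_model):
        """Pixel estimates equal direct model.predict on the same absorbances."""
        A = np.array([0.3, 0.5, 0.4, 0.2])
        R = (10.0 ** -A)[:, None, None] * np.ones((4, 2, 2))
        maps = est.estimate_maps(stack_from_reflectance(R), small_model)
        b_ref, cth_ref = small_model.predict(A)
        assert maps.b_map[1, 1] == pytest.approx(float(b_ref), rel=1e-12)
        assert maps.cth_map[1, 1] == pytest.approx(float(cth_ref), rel=1e-12)

    def test_invariant_to_joint_gain(self, toy_model):
        """A global gain applied to Is and Iw together cancels exactly."""
        rng = np.random.default_rng(0)
        R = rng.uniform(0.2, 0.8, size=(4, 5, 5))
        m1 = est.estimate_maps(stack_from_reflectance(R, white=1.0), toy_model)
        m2 = est.estimate_maps(stack_from_reflectance(R, white=3.7), toy_model)
        np.testing.assert_allclose(m1.cth_map, m2.cth_map, rtol=1e-12)
        np.testing.assert_allclose(m1.b_map, m2.b_map, rtol=1e-12)


class TestRelativeChange:
    def _maps(self, cth, b, shape=(4, 4)):
        return est.ParameterMaps(
            cth_map=np.full(shape, float(cth)),
            b_map=np.full(shape, float(b)),
            valid_mask=np.ones(shape, bool),
        )

    def test_constant_series_gives_zero_deltas(self):
        series = [self._maps(0.5, 3.0) for _ in range(4)]
        rois = {"roi1": np.ones((4, 4), bool)}
        tc = est.relative_change(series, rois)
        np.testing.assert_allclose(tc.delta_cth_pct, 0.0)
        np.testing.assert_allclose(tc.delta_b_pct, 0.0)

    def test_doubling_gives_plus_hundred_percent(self):
        series = [self._maps(0.4, 3.0), self._maps(0.8, 3.0)]
        tc = est.relative_change(series, {"r": np.ones((4, 4), bool)})
        assert tc.delta_cth_pct[1, 0] == pytest.approx(100.0)

    def test_ten_percent_scattering_drop(self):
        series = [self._maps(0.4, 3.0), self._maps(0.4, 2.7)]
        tc = est.relative_change(series, {"r": np.ones((4, 4), bool)})
        assert tc.delta_b_pct[1, 0] == pytest.approx(-10.0)

    def test_baseline_entries_exactly_zero(self):
        series = [self._maps(0.41, 2.97), self._maps(0.53, 3.1), self._maps(0.6, 3.2)]
        tc = est.relative_change(series, {"r": np.ones((4, 4), bool)}, baseline_index=1)
        assert tc.delta_cth_pct[1, 0] == 0.0 and tc.delta_b_pct[1, 0] == 0.0

    def test_zero_baseline_flagged(self):
        series = [self._maps(0.0, 3.0), self._maps(0.5, 3.0)]
        with pytest.raises(ValueError, match="baseline"):
            est.relative_change(series, {"r": np.ones((4, 4), bool)})

    def test_frame_layout(self):
        series = [self._maps(0.4, 3.0), self._maps(0.6, 3.0)]
        tc = est.relative_change(series, {"r": np.ones((4, 4), bool)}, times=[0, 6])
        df = tc.to_frame()
        assert set(df.columns) == {
            "time", "roi", "mean_cth", "mean_b", "delta_cth_pct", "delta_b_pct"
        }
        assert df[df.time == 6].delta_cth_pct.iloc[0] == pytest.approx(50.0)


class TestFileIO:
    def test_stack_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        stack = stack_from_reflectance(
            rng.uniform(0.2, 0.8, (4, 6, 5)), white=0.9, timestamp="week3"
        )
        sidecar = est.save_stack(stack, tmp_path, name="wk3")
        back = est.load_stack(sidecar)
        np.testing.assert_allclose(back.images, stack.images, rtol=1e-6)
        assert back.timestamp == "week3"
        assert back.wavelengths == ISOSBESTIC_WAVELENGTHS

    def test_maps_roundtrip(self, tmp_path):
        maps = est.ParameterMaps(
            cth_map=np.random.default_rng(2).uniform(0, 1, (5, 5)),
            b_map=np.full((5, 5), 3.0),
            valid_mask=np.eye(5, dtype=bool),
        )
        est.save_maps(maps, tmp_path)
        back = est.load_maps(tmp_path)
        np.testing.assert_allclose(back.b_map, 3.0)
        assert back.valid_mask.sum() == 5
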