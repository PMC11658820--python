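import numpy as np
import pytest

from sorghumnet import (
    ImageRecord,
    PointSet,
    PolyModel,
    ValidationError,
    apply_mask,
    build_network,
    count_panicle_side,
    fit_panicle_model,
    predict_total,
    split_patches,
    symmetry_report,
)
from sorghumnet.panicle_pipeline import (
    GrainCountEstimate,
    PanicleRecord,
    patch_heights,
    read_estimates_csv,
    split_point_set,
    write_estimates_csv,
)


class TestApplyMask:
    def test_all_ones_mask_is_identity(self, rng):
        px = rng.integers(0, 255, (10, 8, 3), dtype=np.uint8)
        rec = ImageRecord("a", px, np.ones((10, 8), dtype=bool))
        np.testing.assert_array_equal(apply_mask(rec).pixels, px)

    def test_all_zeros_mask_blacks_out(self, rng):
        px = rng.integers(1, 255, (10, 8, 3), dtype=np.uint8)
        rec = ImageRecord("a", px, np.zeros((10, 8), dtype=bool))
        assert apply_mask(rec).pixels.sum() == 0

    def test_checkerboard_preserves_foreground_exactly(self, rng):
        px = rng.integers(0, 255, (10, 8, 3), dtype=np.uint8)
        mask = np.indices((10, 8)).sum(axis=0) % 2 == 0
        out = apply_mask(ImageRecord("a", px, mask)).pixels
        np.testing.assert_array_equal(out[mask], px[mask])
        assert out[~mask].sum() == 0

    def test_missing_mask_rejected(self, rng):
        rec = ImageRecord("a", rng.integers(0, 255, (10, 8, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            apply_mask(rec)


class TestPatches:
    def test_equal_division(self):
        assert patch_heights(300) == (100, 100, 100)

    def test_remainder_goes_to_bottom(self):
        assert patch_heights(301) == (100, 100, 101)
        assert patch_heights(302) == (100, 100, 102)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            patch_heights(2)

    def test_heights_sum_for_all_sizes(self):
        for h in range(3, 1001):
            assert sum(patch_heights(h)) == h

    def test_raw_patches_tile_source_exactly(self, rng):
        px = rng.integers(0, 255, (100, 40, 3), dtype=np.uint8)
        ps = split_patches(ImageRecord("a", px), target_size=(32, 32))
        np.testing.assert_array_equal(np.vstack(ps.raw), px)
        assert all(p.shape == (32, 32, 3) for p in ps.resized)

    def test_point_set_partition(self):
        pts = np.array([[1.0, 5.0], [1.0, 40.0], [1.0, 75.0], [1.0, 99.0]])
        ps = PointSet("a", 10, 100, pts)
        parts = split_point_set(ps, (33, 33, 34))
        assert [p.n_points for p in parts] == [1, 1, 2]
        # y shifted into the local patch frame
        assert parts[1].points[0, 1] == 40.0 - 33
        assert parts[2].points[1, 1] == 99.0 - 66


class TestCountPanicleSide:
    def test_total_is_sum_of_patches(self, tiny_arch, rng):
        handle = build_network(tiny_arch, seed=0)
        px = rng.integers(0, 255, (60, 30, 3), dtype=np.uint8)
        mask = np.zeros((60, 30), dtype=bool)
        mask[10:50, 8:22] = True
        est = count_panicle_side(ImageRecord("a", px, mask), handle, side="A")
        assert est.total_visible == sum(est.patch_counts)
        assert est.total_visible >= 0

    def test_missing_mask_propagates(self, tiny_arch, rng):
        handle = build_network(tiny_arch, seed=0)
        px = rng.integers(0, 255, (60, 30, 3), dtype=np.uint8)
        with pytest.raises(ValidationError):
            count_panicle_side(ImageRecord("a", px), handle)


class TestPolyModel:
    def test_noiseless_quadratic_recovered_exactly(self, rng):
        x = np.linspace(1, 20, 20)
        y = 2 * x ** 2 + 3 * x + 100
        model = fit_panicle_model(list(zip(x, y)), degree=2, seed=0)
        np.testing.assert_allclose(model.coefficients, [100, 3, 2], atol=1e-6)
        assert abs(model.fit_metrics.r2 - 1.0) < 1e-9

    @pytest.mark.parametrize("degree", [1, 3, 4])
    def test_noiseless_recovery_any_degree(self, degree, rng):
        coeffs = rng.uniform(-2, 2, degree + 1)
        x = np.linspace(0, 10, 4 * (degree + 2))
        y = np.polynomial.polynomial.polyval(x, coeffs)
        model = fit_panicle_model(list(zip(x, y)), degree=degree, seed=1)
        np.testing.assert_allclose(model.coefficients, coeffs, atol=1e-6)

    def test_degree_zero_is_train_mean(self):
        x = np.arange(10.0)
        y = np.array([5.0] * 5 + [15.0] * 5)
        model = fit_panicle_model(list(zip(x, y)), degree=0, seed=0)
        rng = np.random.default_rng(0)
        order = rng.permutation(10)
        train_idx = order[:7]
        assert abs(model.coefficients[0] - y[train_idx].mean()) < 1e-9

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_panicle_model([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0), (5.0, 4.0)],
                              degree=1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_panicle_model([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)], degree=2)

    def test_json_round_trip(self):
        model = PolyModel(degree=2, coefficients=np.array([100.0, 3.0, 2.0]))
        back = PolyModel.from_json(model.to_json(seed=5))
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.degree == 2

    def test_coefficient_length_checked(self):
        with pytest.raises(ValidationError):
            PolyModel(degree=2, coefficients=np.array([1.0, 2.0]))


class TestPredictTotal:
    def test_worked_example(self):
        model = PolyModel(degree=2, coefficients=np.array([100.0, 3.0, 2.0]))
        assert predict_total(model, 10.0) == 330.0

    def test_zero_input_gives_intercept(self):
        model = PolyModel(degree=2, coefficients=np.array([100.0, 3.0, 2.0]))
        assert predict_total(model, 0.0) == 100.0

    def test_negative_prediction_clipped(self):
        model = PolyModel(degree=0, coefficients=np.array([-50.0]))
        assert predict_total(model, 3.0) == 0.0

    def test_matches_horner_evaluation(self, rng):
        coeffs = rng.uniform(-1, 1, 4)
        model = PolyModel(degree=3, coefficients=coeffs)
        xs = rng.uniform(0, 100, 1000)
        expected = np.zeros_like(xs)
        for c in coeffs[::-1]:
            expected = expected * xs + c
        np.testing.assert_allclose(predict_total(model, xs),
                                   np.maximum(expected, 0.0), rtol=1e-12)


def make_record(pid, a, b, total=1000):
    ea = GrainCountEstimate(f"{pid}_A", "A", (a / 2, a / 4, a / 4))
    eb = GrainCountEstimate(f"{pid}_B", "B", (b / 2, b / 4, b / 4))
    return PanicleRecord(pid, ea, eb, total)


class TestSymmetryReport:
    def test_identical_sides_zero(self):
        recs = [make_record("p1", 100, 100), make_record("p2", 250, 250)]
        rep = symmetry_report(recs)
        assert rep.mae == 0 and rep.mse == 0 and rep.rmse == 0

    def test_hand_worked_example(self):
        recs = [make_record("p1", 100, 110), make_record("p2", 200, 190)]
        rep = symmetry_report(recs)
        assert rep.mae == 10 and rep.mse == 100 and rep.rmse == 10

    def test_agrees_with_evaluate_counts(self, rng):
        from sorghumnet import evaluate_counts
        a = rng.uniform(100, 500, 10)
        b = rng.uniform(100, 500, 10)
        recs = [make_record(f"p{i}", a[i], b[i]) for i in range(10)]
        rep = symmetry_report(recs)
        ref = evaluate_counts(a, b)
        assert abs(rep.mae - ref.mae) < 1e-9
        assert abs(rep.rmse - ref.rmse) < 1e-9

    def test_missing_side_names_panicle(self):
        rec = PanicleRecord("p9", GrainCountEstimate("x", "A", (1, 1, 1)), None, 10)
        with pytest.raises(ValidationError, match="p9"):
            symmetry_report([rec])


def test_estimates_csv_round_trip(tmp_path):
    rows = [{"panicle_id": "p1", "side": "A", "patch1": 10.0, "patch2": 20.0,
             "patch3": 30.0, "total_visible": 60.0, "predicted_total": 130.0,
             "observed_total": 120}]
    path = tmp_path / "est.csv"
    write_estimates_csv(rows, path)
    df = read_estimates_csv(path)
    assert len(df) == 1
    assert df.loc[0, "total_visible"] == 60.0


class TestCalibrationRecords:
    def _frame(self):
        import pandas as pd
        return pd.DataFrame({
            "panicle_id": ["p1", "p1", "p2", "p2"],
            "side": ["A", "B", "A", "B"],
            "total_visible": [100.0, 120.0, 300.0, 280.0],
            "observed_total": [240, 240, 600, 600],
        })

    def test_single_mode_uses_each_side(self):
        from sorghumnet.panicle_pipeline import calibration_records
        recs = calibration_records(self._frame(), mode="single")
        assert len(recs) == 4

    def test_mean_mode_averages_sides(self):
        from sorghumnet.panicle_pipeline import calibration_records
        recs = dict(calibration_records(self._frame(), mode="mean"))
        assert recs[110.0] == 240 and recs[290.0] == 600

    def test_unknown_mode_rejected(self):
        from sorghumnet.panicle_pipeline import calibration_records
        with pytest.raises(ValidationError):
            calibration_records(self._frame(), mode="median")
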