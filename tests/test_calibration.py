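"""Error statistics and the shift/linear/scale correction fits."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photoredox.calibration import (
    AlignmentError,
    CorrectionModel,
    DegenerateFitError,
    apply_correction,
    fit_linear,
    fit_scale,
    fit_shift,
    fit_universal_shift,
    mae,
)


def grid_shift_oracle(pred, ref, step=1e-4):
    """Exhaustive search for the MAE-minimizing shift."""
    resid = np.asarray(ref) - np.asarray(pred)
    grid = np.arange(resid.min() - 0.1, resid.max() + 0.1, step)
    losses = np.abs(resid[None, :] - grid[:, None] + 0.0).mean(axis=1)
    losses = np.abs((np.asarray(pred)[None, :] + grid[:, None])
                    - np.asarray(ref)[None, :]).mean(axis=1)
    return float(grid[np.argmin(losses)]), float(losses.min())


class TestMae:
    def test_identity_is_zero(self):
        assert mae([1.0, 2.0], [1.0, 2.0], n_boot=100).mae == 0.0

    def test_constant_offset(self):
        ref = [0.5, 1.0, -2.0]
        pred = [r + 0.2 for r in ref]
        assert mae(pred, ref, n_boot=100).mae == pytest.approx(0.2)

    def test_matches_loop_oracle(self, rng):
        pred, ref = rng.normal(size=30), rng.normal(size=30)
        loop = sum(abs(p - r) for p, r in zip(pred, ref)) / 30
        assert mae(pred, ref, n_boot=100).mae == pytest.approx(loop, abs=1e-12)

    def test_ci_brackets_mae(self, rng):
        pred, ref = rng.normal(size=40), rng.normal(size=40)
        st_ = mae(pred, ref, n_boot=500)
        assert st_.ci_low <= st_.mae <= st_.ci_high

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            mae([1.0], [1.0, 2.0])

    def test_by_group_substats(self, rng):
        pred, ref = rng.normal(size=20), rng.normal(size=20)
        groups = ["a"] * 10 + ["b"] * 10
        st_ = mae(pred, ref, n_boot=100, groups=groups)
        assert set(st_.by_group) == {"a", "b"}
        assert st_.by_group["a"].n == 10


class TestFitShift:
    def test_constant_residual(self):
        pred = [1.0, 2.0, 3.0]
        ref = [p + 0.2 for p in pred]
        assert fit_shift(pred, ref).shift_b == pytest.approx(0.2)

    def test_median_not_mean(self):
        pred = [0.0, 0.0, 0.0]
        ref = [0.0, 1.0, 10.0]
        assert fit_shift(pred, ref).shift_b == pytest.approx(1.0)

    def test_improves_mae(self, rng):
        pred = rng.normal(size=50)
        ref = pred + 0.3 + rng.normal(0, 0.1, size=50)
        b = fit_shift(pred, ref).shift_b
        assert mae(pred + b, ref, n_boot=50).mae <= mae(
            pred, ref, n_boot=50).mae

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_grid_search_oracle(self, seed):
        """Closed-form median shift matches exhaustive 1e-4 grid search."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        pred = rng.normal(size=n)
        ref = pred + rng.normal(0.2, 0.3, size=n)
        model = fit_shift(pred, ref)
        b_grid, loss_grid = grid_shift_oracle(pred, ref)
        loss_fit = np.abs((pred + model.shift_b) - ref).mean()
        assert loss_fit <= loss_grid + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(AlignmentError):
            fit_shift([], [])


class TestUniversalShift:
    def test_single_method_degenerates_to_fit_shift(self, rng):
        pred = rng.normal(size=20)
        ref = pred + rng.normal(0.1, 0.2, size=20)
        uni = fit_universal_shift({"a": pred}, {"a": ref})
        assert uni.shift_b == pytest.approx(fit_shift(pred, ref).shift_b)
        assert uni.scope == "universal"

    def test_pooled_median_between_method_medians(self, rng):
        pred_a = rng.normal(size=50)
        pred_b = rng.normal(size=50)
        ref_a, ref_b = pred_a + 0.1, pred_b + 0.3
        uni = fit_universal_shift({"a": pred_a, "b": pred_b},
                                  {"a": ref_a, "b": ref_b})
        assert 0.1 <= uni.shift_b <= 0.3
        # grid oracle over the pooled residuals: the fitted shift achieves
        # the grid optimum (the minimizer itself may sit on a plateau)
        pred = np.r_[pred_a, pred_b]
        ref = np.r_[ref_a, ref_b]
        _, loss_grid = grid_shift_oracle(pred, ref)
        assert np.abs(pred + uni.shift_b - ref).mean() <= loss_grid + 1e-9

    def test_planted_bias_recovered(self, rng):
        pred = rng.normal(size=200)
        ref = pred + 0.2 + rng.normal(0, 0.15, size=200)
        uni = fit_universal_shift({"m": pred}, {"m": ref})
        assert uni.shift_b == pytest.approx(0.2, abs=0.03)


class TestFitLinear:
    def test_exact_line(self):
        pred = np.linspace(-2, 2, 15)
        ref = 1.1 * pred - 0.05
        model = fit_linear(pred, ref)
        assert model.slope == pytest.approx(1.1, abs=1e-9)
        assert model.intercept == pytest.approx(-0.05, abs=1e-9)

    def test_never_worse_than_shift(self, rng):
        pred = rng.normal(size=30)
        ref = 1.2 * pred + 0.1 + rng.normal(0, 0.1, size=30)
        lin = fit_linear(pred, ref)
        shf = fit_shift(pred, ref)
        mae_lin = np.abs(lin.slope * pred + lin.intercept - ref).mean()
        mae_shf = np.abs(pred + shf.shift_b - ref).mean()
        assert mae_lin <= mae_shf + 1e-9

    def test_matches_coarse_grid_oracle(self, rng):
        pred = rng.normal(size=20)
        ref = 0.9 * pred - 0.2 + rng.normal(0, 0.05, size=20)
        model = fit_linear(pred, ref)
        slopes = np.arange(0.5, 1.5, 0.01)
        intercepts = np.arange(-0.6, 0.2, 0.01)
        best = min(
            np.abs(s * pred + i - ref).mean()
            for s in slopes for i in intercepts
        )
        ours = np.abs(model.slope * pred + model.intercept - ref).mean()
        assert ours <= best + 1e-9

    def test_constant_pred_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_linear([1.0, 1.0, 1.0], [0.0, 0.5, 1.0])


class TestFitScale:
    def test_exact_recovery(self, rng):
        e_abs = rng.uniform(2.0, 3.5, size=20)
        model = fit_scale(e_abs, 0.91 * e_abs)
        assert model.scale_k == pytest.approx(0.91, abs=1e-12)

    def test_unit_scale(self, rng):
        e_abs = rng.uniform(2.0, 3.5, size=10)
        assert fit_scale(e_abs, e_abs).scale_k == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_vs_grid(self, rng):
        e_abs = rng.uniform(2.0, 3.5, size=100)
        e00 = 0.91 * e_abs + rng.normal(0, 0.1, size=100)
        model = fit_scale(e_abs, e00)
        assert model.scale_k == pytest.approx(0.91, abs=0.02)
        grid = np.arange(0.5, 1.2, 1e-4)
        best = grid[np.argmin([np.abs(e00 - k * e_abs).mean() for k in grid])]
        assert np.abs(e00 - model.scale_k * e_abs).mean() <= np.abs(
            e00 - best * e_abs).mean() + 1e-9

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_scale([-1.0, 2.0], [1.0, 2.0])


class TestApplyCorrection:
    def test_zero_shift_identity(self):
        model = CorrectionModel(kind="shift", shift_b=0.0, fitted_on_n=3)
        assert apply_correction(1.234, model) == pytest.approx(1.234)

    def test_universal_shift_literal(self):
        model = CorrectionModel(kind="shift", shift_b=0.2, fitted_on_n=10)
        assert apply_correction(2.0, model) == pytest.approx(2.2)

    def test_scale_arithmetic(self):
        model = CorrectionModel(kind="scale", scale_k=0.91, fitted_on_n=5)
        assert apply_correction(2.5, model) == pytest.approx(2.275)

    def test_scope_mismatch_rejected(self):
        model = CorrectionModel(kind="shift", shift_b=0.1,
                                scope=("M062X", "M+/M"), fitted_on_n=4)
        with pytest.raises(ValueError, match="method"):
            apply_correction(1.0, model, method_tag="B3LYP", couple="M+/M")

    def test_potential_record_marked_calibrated(self):
        from photoredox.redox_core import Couple, PotentialRecord, State
        p = PotentialRecord("m", Couple.M_PLUS_OVER_M, State.GROUND, "MeCN",
                            2.0)
        model = CorrectionModel(kind="shift", shift_b=0.2, fitted_on_n=10)
        out = apply_correction(p, model)
        assert out.value == pytest.approx(2.2)
        assert out.calibrated

    def test_model_kind_field_exclusivity(self):
        with pytest.raises(ValueError):
            CorrectionModel(kind="shift", shift_b=0.1, scale_k=0.9)

    def test_json_round_trip(self):
        model = CorrectionModel(kind="linear", slope=1.1, intercept=-0.05,
                                scope=("M062X", "M/M-"), fitted_on_n=37,
                                ci_seed=7)
        assert CorrectionModel.from_json(model.to_json()) == model
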