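"""Tests of the factorial grid, error surface and correction validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ftjump import (
    GridSpec,
    JumpCondition,
    build_grid,
    run_grid,
    simulate_condition,
    validate_correction,
)
from ftjump.flight import estimated_height_closed_form, true_height_from_flight
from ftjump.simulation import CSV_COLUMNS


class TestGridSpec:
    def test_default_design(self):
        spec = GridSpec()
        assert spec.n_conditions == 16400
        statures = spec.statures()
        assert statures[0] == pytest.approx(1.435)
        assert statures[-1] == pytest.approx(1.984)
        assert len(statures) == 100
        assert np.diff(statures) == pytest.approx((1.984 - 1.435) / 99)

    def test_rejects_empty_axes(self):
        with pytest.raises(ValueError):
            GridSpec(ankle_changes=())
        with pytest.raises(ValueError):
            GridSpec(jump_heights=())

    def test_rejects_change_exceeding_takeoff_angle(self):
        with pytest.raises(ValueError):
            GridSpec(takeoff_angle=30.0, ankle_changes=(0.0, 40.0))

    def test_rejects_invalid_condition(self):
        with pytest.raises(ValueError):
            JumpCondition(H=1.75, h=0.0, alpha_to=40.0, alpha_land=0.0)
        with pytest.raises(ValueError):
            JumpCondition(H=1.75, h=0.30, alpha_to=40.0, alpha_land=-5.0)


class TestBuildGrid:
    def test_single_condition_grid(self):
        spec = GridSpec(
            stature_min=1.75, stature_max=1.75, stature_count=1,
            ankle_changes=(0.0,), jump_heights=(0.30,),
        )
        grid = build_grid(spec)
        assert len(grid) == 1
        assert grid[0] == JumpCondition(H=1.75, h=0.30, alpha_to=40.0, alpha_land=40.0)

    def test_row_order_stature_outer_height_inner(self, small_spec):
        grid = build_grid(small_spec)
        assert len(grid) == small_spec.n_conditions
        # first block: lowest stature, first change, heights cycling fastest
        assert grid[0].h == 0.10 and grid[1].h == 0.20
        assert grid[0].H == grid[1].H == small_spec.stature_min
        per_stature = len(small_spec.ankle_changes) * len(small_spec.jump_heights)
        assert grid[per_stature].H > grid[0].H


class TestSimulateCondition:
    def test_zero_change_is_error_free(self):
        rec = simulate_condition(JumpCondition(1.75, 0.30, 40.0, 40.0))
        assert rec.h_error_pct == 0.0
        assert rec.h_diff_m == 0.0
        assert rec.h_corrected_m == pytest.approx(0.30, abs=1e-12)

    def test_tall_low_jump_flat_landing(self):
        rec = simulate_condition(JumpCondition(1.984, 0.10, 40.0, 0.0))
        assert rec.h_est_m == pytest.approx(0.1594, abs=0.0005)
        assert rec.h_error_pct == pytest.approx(59.4, abs=0.5)

    def test_average_stature_cases(self):
        rec40 = simulate_condition(JumpCondition(1.71, 0.30, 40.0, 0.0))
        rec20 = simulate_condition(JumpCondition(1.71, 0.30, 40.0, 20.0))
        assert rec40.h_error_pct == pytest.approx(18.3, abs=0.3)
        assert rec20.h_error_pct == pytest.approx(8.0, abs=0.3)


class TestRunGrid:
    def test_grid_shape_and_zero_change_rows(self, default_grid):
        df = default_grid.records
        assert len(df) == 16400
        zero = df[df["change_deg"] == 0.0]
        assert len(zero) == 400
        assert (zero["h_error_pct"] == 0.0).all()
        assert np.allclose(zero["h_corrected_m"], zero["jump_height_m"], atol=1e-12)

    def test_max_error_location(self, default_grid):
        argmax = default_grid.argmax_condition()
        assert argmax["stature_m"] == pytest.approx(1.984)
        assert argmax["jump_height_m"] == pytest.approx(0.10)
        assert argmax["change_deg"] == 40.0

    def test_error_at_accessor(self, default_grid):
        val = default_grid.error_at(1.984, 0.10, 40.0)
        assert val == default_grid.max_error()
        with pytest.raises(KeyError):
            default_grid.error_at(1.70, 0.10, 40.0)  # not a grid node

    def test_closed_form_identity_every_row(self, default_grid):
        df = default_grid.records
        expected = (
            np.sqrt(df["jump_height_m"])
            + np.sqrt(df["jump_height_m"] - df["h_diff_m"])
        ) ** 2 / 4
        assert np.allclose(df["h_est_m"], expected, atol=1e-12)

    def test_error_surface_monotonicity(self, default_grid):
        """Error rises with stature and ankle change and falls with jump
        height along every grid slice."""
        df = default_grid.records
        by_stature = df[
            (df["jump_height_m"] == 0.10) & (df["change_deg"] == 40.0)
        ].sort_values("stature_m")["h_error_pct"].to_numpy()
        assert (np.diff(by_stature) > 0).all()
        by_change = df[
            (np.isclose(df["stature_m"], 1.984)) & (df["jump_height_m"] == 0.10)
        ].sort_values("change_deg")["h_error_pct"].to_numpy()
        assert (np.diff(by_change) > 0).all()
        by_height = df[
            (np.isclose(df["stature_m"], 1.984)) & (df["change_deg"] == 40.0)
        ].sort_values("jump_height_m")["h_error_pct"].to_numpy()
        assert (np.diff(by_height) < 0).all()

    def test_correction_efficacy_every_row(self, default_grid):
        df = default_grid.records
        changed = df[df["change_deg"] > 0]
        resid_corrected = (changed["h_corrected_m"] - changed["jump_height_m"]).abs()
        resid_estimate = (changed["h_est_m"] - changed["jump_height_m"]).abs()
        assert (resid_corrected < resid_estimate).all()

    def test_correction_residual_below_two_millimetres(self, default_grid):
        df = default_grid.records
        assert (df["h_corrected_m"] - df["jump_height_m"]).abs().max() < 0.002

    def test_csv_determinism(self, small_spec, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_grid(small_spec).to_csv(p1)
        run_grid(small_spec).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_header_and_round_trip(self, small_spec, tmp_path):
        path = tmp_path / "grid.csv"
        result = run_grid(small_spec)
        result.to_csv(path)
        assert path.read_text().splitlines()[0] == ",".join(CSV_COLUMNS)
        back = pd.read_csv(path)
        assert len(back) == len(result.records)
        for col in CSV_COLUMNS:
            assert np.allclose(back[col], result.records[col], atol=5e-7)


class TestValidateCorrection:
    def test_default_grid_regression(self, default_grid):
        reg = validate_correction(default_grid, h_max=0.20)
        assert reg.n == 8200
        assert reg.df_residual == 8198
        assert 0 <= reg.r_squared <= 1
        assert reg.r_squared > 0.999
        assert reg.slope == pytest.approx(1.0, abs=0.01)
        assert reg.intercept == pytest.approx(0.0, abs=0.001)

    def test_exact_model_hdiff_gives_perfect_regression(self, small_spec):
        """Correcting with the exact segment-model h_diff (instead of the
        anthropometric estimate) recovers true height identically."""
        df = run_grid(small_spec).records
        recovered = [
            true_height_from_flight(ft, hd)[0]
            for ft, hd in zip(df["ft_s"], df["h_diff_m"])
        ]
        fit = stats.linregress(df["jump_height_m"], recovered)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.rvalue**2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_rows_rejected(self, small_spec):
        grid = run_grid(small_spec)
        with pytest.raises(ValueError, match="at least 3"):
            validate_correction(grid, h_max=0.01)

    def test_summary_contents(self, small_spec):
        summary = run_grid(small_spec).summary()
        assert summary["n_conditions"] == small_spec.n_conditions
        assert summary["max_error_pct"] == pytest.approx(
            summary["argmax"]["h_error_pct"]
        )
        assert summary["correction_regression"]["df_residual"] == (
            summary["correction_regression"]["n"] - 2
        )
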