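"""Quantitation chain: normalization, weighted fit, LOD, linear range, back-calc."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import srmquant as sq
from srmquant.quantify import (
    FLAG_ABOVE_ULOQ,
    FLAG_BELOW_LLOQ,
    FLAG_BELOW_LOD,
    FLAG_OK,
    STATUS_MISSING_ISTD,
    STATUS_OK,
    STATUS_ZERO_ISTD,
    CalibrationCurve,
    CalibrationError,
    LodResult,
    NoLinearRangeError,
    apply_calibration,
    calibrate_panel,
    determine_linear_range,
    determine_lod,
    fit_calibration,
    normalize_to_istd,
    quantify_study,
    weighted_linear_fit,
)
from srmquant.simulate import (
    CohortEffectSpec,
    ResponseModel,
    simulate_calibration_series,
    simulate_cohort,
    synthetic_panel,
)


def _peak_rows(entity, pairs, sample="S1", injection=1):
    """pairs: list of (channel, area)."""
    return pd.DataFrame(
        [
            {
                "sample_id": sample,
                "injection_index": injection,
                "entity": entity,
                "channel": ch,
                "retention_time_min": 1.0,
                "peak_area": area,
                "signal_to_noise": 10.0,
            }
            for ch, area in pairs
        ]
    )


class TestNormalizeToIstd:
    def test_simple_ratio(self, fixture_panel):
        peaks = _peak_rows("Ala", [("analyte", 1000.0), ("istd", 500.0)])
        out = normalize_to_istd(peaks, fixture_panel)
        assert out["response"].iloc[0] == pytest.approx(2.0)
        assert bool(out["normalized"].iloc[0]) is True

    def test_istd_free_entity_passes_raw_area(self, fixture_panel):
        peaks = _peak_rows("GBB", [("analyte", 1234.0)])
        out = normalize_to_istd(peaks, fixture_panel)
        assert out["response"].iloc[0] == pytest.approx(1234.0)
        assert bool(out["normalized"].iloc[0]) is False
        assert out["status"].iloc[0] == STATUS_OK

    def test_merged_entity_normalized_against_shared_istd(self, fixture_panel):
        # the merged dimethylarginine entity uses its single shared ISTD
        assert fixture_panel.entity("ADMA and SDMA").istd_abbreviation == "d7-ADMA"
        peaks = _peak_rows("ADMA and SDMA", [("analyte", 300.0), ("istd", 100.0)])
        out = normalize_to_istd(peaks, fixture_panel)
        assert out["response"].iloc[0] == pytest.approx(3.0)

    def test_missing_istd_row_produces_error_record(self, fixture_panel):
        peaks = _peak_rows("Ala", [("analyte", 1000.0)])  # no istd row
        out = normalize_to_istd(peaks, fixture_panel)
        assert len(out) == 1  # not silently dropped
        assert out["status"].iloc[0] == STATUS_MISSING_ISTD
        assert np.isnan(out["response"].iloc[0])

    def test_zero_istd_area_flagged_unquantifiable(self, fixture_panel):
        peaks = _peak_rows("Ala", [("analyte", 1000.0), ("istd", 0.0)])
        out = normalize_to_istd(peaks, fixture_panel)
        assert out["status"].iloc[0] == STATUS_ZERO_ISTD
        assert np.isnan(out["response"].iloc[0])

    def test_unknown_entity_rejected(self, fixture_panel):
        peaks = _peak_rows("NotARealMetabolite", [("analyte", 1.0)])
        with pytest.raises(KeyError, match="NotARealMetabolite"):
            normalize_to_istd(peaks, fixture_panel)


class TestWeightedFit:
    def test_noiseless_line_recovered_exactly(self):
        curve = fit_calibration([1, 2, 4, 8, 16], [1, 2, 4, 8, 16], "E", min_points=3)
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(CalibrationError, match="at least 5"):
            fit_calibration([1, 2, 4, 8], [1, 2, 4, 8], "E")

    def test_three_point_exception_via_min_points(self):
        curve = fit_calibration([100, 1000, 10000], [1.0, 10.0, 100.0], min_points=3)
        assert curve.slope == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_statsmodels_wls_oracle(self, seed):
        """Closed-form weighted normal equations vs an independent WLS fit."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 12)
        x = np.sort(rng.uniform(0.5, 1000, size=n))
        y = rng.normal(0.1, 0.05) * x + rng.normal(0, 0.5, size=n)
        slope, intercept, r2 = weighted_linear_fit(x, y, 1.0 / x)
        oracle = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
        assert slope == pytest.approx(oracle.params[1], rel=1e-10)
        assert intercept == pytest.approx(oracle.params[0], rel=1e-10, abs=1e-10)
        assert r2 == pytest.approx(oracle.rsquared, rel=1e-8)


class TestDetermineLod:
    def test_lowest_level_already_detected_reports_below_lowest(self):
        lod = determine_lod([2.5, 5, 10], [5.0, 9.0, 20.0])
        assert lod.status == "below_lowest"
        assert str(lod) == "< 2.5"
        assert lod.detection_threshold == 0.0

    def test_first_level_reaching_snr3(self):
        lod = determine_lod([2.5, 5, 10, 25], [1.0, 2.0, 4.0, 9.0])
        assert lod.status == "value" and lod.concentration == 10.0

    def test_no_level_reaches_snr3_reports_above_highest(self):
        lod = determine_lod([2.5, 5, 10], [1.0, 1.5, 2.0])
        assert lod.status == "above_highest"
        assert str(lod) == "> 10"

    def test_median_aggregation_across_series(self):
        # replicate S/N at the same level aggregates by median: (2, 4, 4) -> 4
        lod = determine_lod([5, 5, 5, 10], [2.0, 4.0, 4.0, 9.0])
        assert lod.status == "below_lowest"


def brute_force_linear_range(levels, responses, min_points=5, band=(0.8, 1.2)):
    """Independent exhaustive scan over all contiguous level runs.

    Re-implements the acceptance rule directly: weighted fit on the run's
    points, per-level back-calculated mean response within the band. Returns
    (lloq, uloq) of the winning run or None.
    """
    x = np.asarray(levels, float)
    y = np.asarray(responses, float)
    distinct = np.unique(x)
    best = None
    for i in range(len(distinct)):
        for j in range(i + min_points, len(distinct) + 1):
            run = distinct[i:j]
            mask = np.isin(x, run)
            xs, ys = x[mask], y[mask]
            w = 1.0 / xs
            W = np.diag(w)
            A = np.column_stack([np.ones_like(xs), xs])
            beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ ys)
            if beta[1] <= 0:
                continue
            ok = True
            for lv in run:
                back = (ys[xs == lv].mean() - beta[0]) / beta[1]
                if not (band[0] * lv <= back <= band[1] * lv):
                    ok = False
                    break
            if not ok:
                continue
            key = (j - i, -i, -j)
            if best is None or key > best[0]:
                best = (key, (run[0], run[-1]))
    return None if best is None else best[1]


class TestLinearRange:
    def test_noise_free_data_keeps_all_19_levels(self):
        levels = np.array(sq.simulate.DEFAULT_LEVELS)
        x = np.concatenate([levels, levels])  # two pooled series
        y = 0.01 * x
        curve = determine_linear_range(x, y, "E")
        assert curve.lloq == levels[0] and curve.uloq == levels[-1]
        assert len(curve.levels_used) == 19

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = np.array(sq.simulate.DEFAULT_LEVELS)
        x = np.concatenate([levels, levels])
        # additive noise dominating low levels + occasional proportional noise
        base_sd = rng.uniform(0.0, 2.0)
        y = 0.01 * x * (1 + rng.normal(0, 0.04, x.size)) + rng.normal(0, base_sd, x.size)
        oracle = brute_force_linear_range(x, y)
        try:
            curve = determine_linear_range(x, y, "E")
        except NoLinearRangeError:
            assert oracle is None
            return
        assert oracle is not None
        assert (curve.lloq, curve.uloq) == (oracle[0], oracle[1])

    def test_mid_run_outlier_truncates_at_longer_side(self):
        levels = np.arange(1.0, 14.0)  # 13 levels
        y = 2.0 * levels
        y[3] = 2.0 * levels[3] * 2.5  # gross outlier at the 4th level
        curve = determine_linear_range(levels, y, "E")
        oracle = brute_force_linear_range(levels, y)
        assert (curve.lloq, curve.uloq) == oracle
        assert curve.lloq == 5.0 and curve.uloq == 13.0  # longer (upper) side kept

    def test_no_qualifying_run_raises(self):
        rng = np.random.default_rng(0)
        levels = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        y = rng.permutation(levels) * 3.0  # scrambled: no run is accurate
        with pytest.raises(NoLinearRangeError):
            determine_linear_range(levels, y, "E")


class TestApplyCalibration:
    def _curve(self, **kw):
        defaults = dict(entity="E", slope=0.01, intercept=0.05, r_squared=1.0,
                        levels_used=(10.0, 100.0, 1000.0),
                        lod=LodResult("value", 10.0), lloq=25.0, uloq=1000.0)
        defaults.update(kw)
        return CalibrationCurve(**defaults)

    def _ratios(self, responses):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(responses))],
                "injection_index": 1,
                "entity": "E",
                "response": responses,
            }
        )

    def test_inversion_identity(self):
        curve = self._curve()
        out = apply_calibration(self._ratios([0.05 + 0.01 * 500.0]), curve)
        assert out["concentration"].iloc[0] == pytest.approx(500.0)
        assert out["flag"].iloc[0] == FLAG_OK

    def test_between_lod_and_lloq_keeps_value_with_flag(self):
        curve = self._curve()
        out = apply_calibration(self._ratios([0.05 + 0.01 * 15.0]), curve)
        assert out["flag"].iloc[0] == FLAG_BELOW_LLOQ
        assert out["concentration"].iloc[0] == pytest.approx(15.0)

    def test_above_uloq_flag(self):
        curve = self._curve()
        out = apply_calibration(self._ratios([0.05 + 0.01 * 2000.0]), curve)
        assert out["flag"].iloc[0] == FLAG_ABOVE_ULOQ

    def test_below_lod_and_negative_backcalc_carry_no_value(self):
        curve = self._curve()
        out = apply_calibration(self._ratios([0.05 + 0.01 * 5.0, 0.0]), curve)
        assert (out["flag"] == FLAG_BELOW_LOD).all()
        assert out["concentration"].isna().all()

    def test_non_positive_slope_rejected(self):
        with pytest.raises(CalibrationError, match="slope"):
            apply_calibration(self._ratios([1.0]), self._curve(slope=-1.0))


class TestRoundTrip:
    def test_noise_free_recovery_within_1e9_relative(self, noise_free_model):
        panel = synthetic_panel(3)
        cal, _ = simulate_calibration_series(panel, models=noise_free_model, seed=0)
        curves = calibrate_panel(cal, panel)
        assert set(curves) == {e.name for e in panel.entities()}
        spec = CohortEffectSpec(n_per_group=5, replicate_cv=0.0, residual_sd_log10=0.3)
        clinical, truth, peaks = simulate_cohort(
            panel, spec, seed=0, models=noise_free_model
        )
        conc = quantify_study(peaks, panel, curves)
        merged = conc.merge(truth.concentrations, on=["sample_id", "entity"])
        in_range = merged[merged["flag"] == FLAG_OK]
        assert len(in_range) > 0
        rel = np.abs(in_range["concentration"] - in_range["true_concentration"])
        rel /= in_range["true_concentration"]
        assert rel.max() < 1e-9

    def test_median_error_under_5pct_proportional_cv(self):
        """Parameter recovery: median |back-calc - true|/true <= 10% at CV 5%."""
        panel = synthetic_panel(5)
        model = ResponseModel(proportional_cv=0.05, baseline_noise_sd=50.0)
        cal, _ = simulate_calibration_series(panel, models=model, seed=11)
        curves = calibrate_panel(cal, panel)
        spec = CohortEffectSpec(n_per_group=15, replicate_cv=0.05)
        clinical, truth, peaks = simulate_cohort(panel, spec, seed=11, models=model)
        conc = quantify_study(peaks, panel, curves)
        merged = conc.merge(truth.concentrations, on=["sample_id", "entity"])
        in_range = merged[merged["flag"] == FLAG_OK]
        rel = (merged_err := np.abs(in_range["concentration"] - in_range["true_concentration"])
               / in_range["true_concentration"])
        assert np.median(rel) <= 0.10

    def test_lloq_monotone_in_baseline_noise(self):
        """More additive noise can only push the LLOQ up (noise grid, fixed seed)."""
        panel = synthetic_panel(1)
        lloqs = []
        for sd in (0.0, 200.0, 800.0, 3200.0):
            model = ResponseModel(proportional_cv=0.02, baseline_noise_sd=sd)
            cal, _ = simulate_calibration_series(panel, models=model, seed=5)
            curves = calibrate_panel(cal, panel)
            lloqs.append(curves[panel.entities()[0].name].lloq)
        assert lloqs == sorted(lloqs)


class TestCalibratePanel:
    def test_fixture_panel_reports_lod_and_range(self, fixture_panel):
        cal, _ = simulate_calibration_series(fixture_panel, seed=7)
        curves = calibrate_panel(cal, fixture_panel)
        assert len(curves) == 30
        for name, curve in curves.items():
            assert curve.lod is not None
            assert curve.lloq <= curve.uloq
            assert 0 <= curve.r_squared <= 1
        # ISTD-free entities are calibrated on raw areas
        assert curves["GBB"].normalized is False
        assert curves["Ala"].normalized is True
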