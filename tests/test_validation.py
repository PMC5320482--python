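"""Calibration, matrix effects, recovery/RSD, LOQ, identification points and
survey aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quechemo import datasets
from quechemo.validation import (
    CalibrationCurve,
    RecoveryResult,
    check_loq,
    classify_me,
    dilution_improvement,
    fit_calibration,
    identification_points,
    matrix_effect,
    recovery_summary,
    summarize_recovery_table,
    survey_summary,
)

LEVELS = (0.1, 1.0, 5.0, 10.0, 50.0, 100.0, 200.0)


class TestCalibration:
    def test_exact_line(self):
        x = np.array(LEVELS)
        curve = fit_calibration(x, 2.0 * x + 1.0)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_too_few_levels(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_calibration([1, 2, 3, 4], [1, 2, 3, 4])

    def test_constant_signal_unusable(self):
        curve = fit_calibration(LEVELS, np.full(7, 5.0))
        assert curve.slope == 0.0
        assert not curve.usable

    def test_proportional_noise_slope_recovery(self, rng):
        """2% proportional noise: mean fitted slope within 1% of truth."""
        x = np.array(LEVELS)
        slopes = []
        for _ in range(200):
            y = 1500.0 * x * (1.0 + rng.normal(0, 0.02, x.size))
            slopes.append(fit_calibration(x, y).slope)
        assert np.mean(slopes) == pytest.approx(1500.0, rel=0.01)


class TestMatrixEffect:
    def test_reference_spot_values(self):
        solvent = datasets.reference_curve("2,4-D", "methanol")
        assert matrix_effect(datasets.reference_curve("2,4-D", "citrus", "ND"),
                             solvent).me_rounded == 60
        assert matrix_effect(datasets.reference_curve("2,4-D", "citrus", "D10"),
                             solvent).me_rounded == 29
        assert matrix_effect(datasets.reference_curve("2,4-D", "lychee", "ND"),
                             solvent).me_rounded == -40

    def test_identical_slopes_neutral(self):
        c = CalibrationCurve(slope=100.0, intercept=0.0, r_squared=1.0)
        me = matrix_effect(c, c)
        assert me.me_percent == 0.0
        assert me.direction == "neutral"
        assert me.category == "none"

    def test_zero_solvent_slope_raises(self):
        c = CalibrationCurve(slope=100.0, intercept=0.0, r_squared=1.0)
        z = CalibrationCurve(slope=0.0, intercept=0.0, r_squared=0.0)
        with pytest.raises(ZeroDivisionError):
            matrix_effect(c, z)

    def test_swap_antisymmetry(self):
        a = CalibrationCurve(slope=150.0, intercept=0.0, r_squared=1.0)
        b = CalibrationCurve(slope=100.0, intercept=0.0, r_squared=1.0)
        me_ab = matrix_effect(a, b).me_percent
        me_ba = matrix_effect(b, a).me_percent
        assert me_ba == pytest.approx(100.0 * (1.0 / (1.0 + me_ab / 100.0) - 1.0))

    @pytest.mark.parametrize(
        "me, expected",
        [(60.0, "strong"), (-14.0, "none"), (35.0, "medium"),
         (20.0, "none"), (-20.0, "none"), (50.0, "medium"), (-50.0, "medium"),
         (50.001, "strong"), (-50.001, "strong"), (20.001, "medium")],
    )
    def test_classification_boundaries(self, me, expected):
        assert classify_me(me) == expected

    @settings(max_examples=100, derandomize=True)
    @given(me=st.floats(-100, 200, allow_nan=False))
    def test_classification_is_total_and_consistent(self, me):
        cat = classify_me(me)
        if abs(me) <= 20:
            assert cat == "none"
        elif abs(me) > 50:
            assert cat == "strong"
        else:
            assert cat == "medium"


class TestDilutionImprovement:
    def _mes(self, values):
        from quechemo.validation import MatrixEffectResult

        return {f"a{i}": MatrixEffectResult(v, classify_me(v),
                                            "suppression" if v < 0 else "enhancement")
                for i, v in enumerate(values)}

    def test_all_decreased(self):
        nd = self._mes([60, -40, 30])
        d10 = self._mes([20, -10, 5])
        assert dilution_improvement(nd, d10) == 100.0

    def test_no_change(self):
        nd = self._mes([60, -40])
        assert dilution_improvement(nd, self._mes([60, -40])) == 0.0

    def test_citrus_reference_values(self):
        nd = self._mes([60, 52, 60, -34, 28])
        d10 = self._mes([29, 26, 31, -14, 17])
        assert dilution_improvement(nd, d10) == 100.0
        assert dilution_improvement(nd, d10, metric="strong_resolved") == 100.0

    def test_analyte_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            dilution_improvement(self._mes([1]), self._mes([1, 2]))


class TestRecovery:
    def _frame(self, per_day):
        rows = []
        for d, vals in enumerate(per_day, start=1):
            for r, v in enumerate(vals, start=1):
                rows.append(dict(day=d, rep=r, recovery_pct=v))
        return pd.DataFrame(rows)

    def test_all_equal(self):
        df = self._frame([[90.0] * 5] * 3)
        res = recovery_summary(df)
        assert res.mean_recovery == 90.0
        assert res.rsd_intra == 0.0
        assert res.rsd_inter == 0.0

    def test_hand_computed_rsd(self):
        day1 = [80.0, 90.0, 100.0, 90.0, 90.0]
        df = self._frame([day1, [90.0] * 5, [90.0] * 5])
        res = recovery_summary(df)
        assert res.rsd_intra == pytest.approx(7.86, abs=5e-3)
        assert res.mean_recovery == pytest.approx(90.0)

    def test_structure_errors(self):
        df = self._frame([[90.0] * 5, [90.0] * 4, [90.0] * 5])
        with pytest.raises(ValueError, match="day 2"):
            recovery_summary(df)
        with pytest.raises(ValueError, match="days"):
            recovery_summary(self._frame([[90.0] * 5] * 2))

    def test_brute_force_oracle(self, rng):
        vals = rng.normal(85, 4, (3, 5))
        res = recovery_summary(self._frame(vals.tolist()))
        assert res.mean_recovery == pytest.approx(vals.mean())
        assert res.rsd_intra == pytest.approx(
            100 * vals[0].std(ddof=1) / vals[0].mean())
        assert res.rsd_inter == pytest.approx(
            100 * vals.std(ddof=1) / vals.mean())

    def test_summarize_table_groups(self, rng):
        frames = []
        for a in ("x", "y"):
            df = self._frame(rng.normal(90, 3, (3, 5)).tolist())
            df["analyte"] = a
            df["matrix"] = "citrus"
            df["level_label"] = "LOQ"
            frames.append(df)
        out = summarize_recovery_table(pd.concat(frames))
        assert len(out) == 2
        assert set(out["analyte"]) == {"x", "y"}


class TestLoq:
    def _res(self, mean, rsd_i=5.0, rsd_e=5.0):
        return RecoveryResult("a", "m", "LOQ", mean, rsd_i, rsd_e)

    def test_lowest_passing_level(self):
        results = {1.0: [self._res(91.9)], 10.0: [self._res(96.5)]}
        assert check_loq([1.0, 10.0], results) == 1.0

    def test_boundary_recovery(self):
        results = {1.0: [self._res(69.9)], 1.5: [self._res(75.0)]}
        assert check_loq([1.0, 1.5], results) == 1.5
        # recovery bounds inclusive, RSD strict
        assert check_loq([1.0], {1.0: [self._res(70.0)]}) == 1.0
        assert check_loq([1.0], {1.0: [self._res(120.0)]}) == 1.0
        assert check_loq([1.0], {1.0: [self._res(90.0, rsd_i=20.0)]}) is None

    def test_no_level_passes(self):
        assert check_loq([1.0, 10.0],
                         {1.0: [self._res(60.0)], 10.0: [self._res(65.0)]}) is None


@pytest.mark.parametrize(
    "n_prec, n_prod, ips, confirmed",
    [(1, 2, 4.0, True), (0, 0, 0.0, False), (1, 1, 2.5, False)],
)
def test_identification_points(n_prec, n_prod, ips, confirmed):
    got_ips, got_conf = identification_points(n_prec, n_prod)
    assert got_ips == ips
    assert got_conf is confirmed


class TestSurvey:
    def test_reference_survey_aggregation(self):
        records = datasets.load_survey_records()
        out = survey_summary(records, datasets.LOQS, datasets.SURVEY_COMMODITY_COUNTS)
        assert out["n_samples"] == 85
        assert out["n_positive"] == 10
        assert out["positive_pct"] == 12
        assert out["per_commodity"]["citrus"]["n_positive"] == 6
        assert out["per_commodity"]["citrus"]["positive_pct"] == 30
        assert out["per_commodity"]["mango"]["n_positive"] == 0
        m = out["max_concentration"]
        assert m["conc_ugkg"] == pytest.approx(12.8)
        assert m["analyte"] == "carbendazim"
        assert m["commodity"] == "citrus"

    def test_positive_counts_match_brute_force(self):
        records = datasets.load_survey_records()
        out = survey_summary(records, datasets.LOQS, datasets.SURVEY_COMMODITY_COUNTS)
        brute = set()
        for _, r in records.iterrows():
            c = pd.to_numeric(r["conc_ugkg"], errors="coerce")
            if not pd.isna(c) and c >= datasets.LOQS[r["analyte"]]:
                brute.add(r["sample_id"])
        assert out["n_positive"] == len(brute)

    def test_empty_records(self):
        empty = pd.DataFrame(columns=["sample_id", "commodity", "analyte", "conc_ugkg"])
        out = survey_summary(empty, datasets.LOQS, {"citrus": 5})
        assert out["n_positive"] == 0
        assert out["max_concentration"] is None

    def test_unknown_commodity_raises(self):
        records = pd.DataFrame([dict(sample_id="s1", commodity="durian",
                                     analyte="carbendazim", conc_ugkg=5.0)])
        with pytest.raises(ValueError, match="durian"):
            survey_summary(records, datasets.LOQS, {"citrus": 5})

    def test_mrl_exceedance(self):
        records = pd.DataFrame([
            dict(sample_id="s1", commodity="citrus", analyte="carbendazim",
                 conc_ugkg=6000.0),
            dict(sample_id="s2", commodity="citrus", analyte="carbendazim",
                 conc_ugkg=12.8),
        ])
        mrl = pd.DataFrame([dict(analyte="carbendazim", commodity="citrus",
                                 mrl_mgkg=5.0)])
        out = survey_summary(records, datasets.LOQS, {"citrus": 5}, mrl=mrl)
        assert len(out["mrl_exceedances"]) == 1
        assert out["mrl_exceedances"][0]["sample_id"] == "s1"


def test_calibration_inverse_variance_weighting_option(rng):
    """1/x weighting reproduces the exact line and down-weights the top
    level relative to OLS under proportional noise."""
    x = np.array(LEVELS)
    exact = fit_calibration(x, 3.0 * x + 2.0, weighting="1/x")
    assert exact.slope == pytest.approx(3.0)
    assert exact.intercept == pytest.approx(2.0)
    y = 3.0 * x + 2.0
    y[-1] *= 1.5  # gross error at the top level
    ols = fit_calibration(x, y)
    wls = fit_calibration(x, y, weighting="1/x")
    assert abs(wls.slope - 3.0) < abs(ols.slope - 3.0)
    with pytest.raises(ValueError, match="unknown weighting"):
        fit_calibration(x, y, weighting="quadratic")
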