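"""The synthetic data generator: determinism, planted structure, and
statistical calibration of each simulated stage."""

import numpy as np
import pandas as pd
import pytest

from quechemo import pipeline
from quechemo.designs import generate_ccd, generate_plackett_burman
from quechemo.rsm import fit_quadratic
from quechemo.screening import main_effects, pure_error
from quechemo.synthetic import (
    ANALYTES,
    COMMODITIES,
    make_default_truth,
    simulate_calibration,
    simulate_doe,
    simulate_recovery,
    simulate_survey,
    surface_value,
)
from quechemo.validation import fit_calibration, matrix_effect, recovery_summary


class TestTruth:
    def test_same_seed_identical_spec(self):
        assert make_default_truth(3) == make_default_truth(3)

    def test_truth_independent_of_seed(self):
        a, b = make_default_truth(1), make_default_truth(2)
        assert a.surfaces == b.surfaces
        assert a.me_factor == b.me_factor

    def test_gcb_sign_structure(self, truth):
        negatives = [a for a in ANALYTES if truth.surfaces[a]["gcb"] < 0]
        assert len(negatives) == 3
        assert "2,4-D" not in negatives and "thiabendazole" not in negatives

    def test_surface_maxima_interior_in_hcl_boundary_in_gcb(self, truth):
        for a in ANALYTES:
            c = truth.surfaces[a]
            x_hcl = -c["hcl"] / (2 * c["hcl^2"])
            assert -1 < x_hcl < 1
            if c["gcb"] < 0:
                # linear in gcb: maximum on the low boundary of the cube
                grid = np.linspace(-1, 1, 5)
                pts = np.column_stack([np.zeros(5), np.zeros(5), grid])
                y = surface_value(c, ["toluene", "hcl", "gcb"], pts)
                assert y.argmax() == 0


class TestSimulateDoe:
    def test_determinism(self, ccd_design, truth):
        a = simulate_doe(ccd_design, truth, seed=5)
        b = simulate_doe(ccd_design, truth, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_doe(ccd_design, truth, seed=6)
        assert not np.allclose(a[ANALYTES[0]], c[ANALYTES[0]])

    def test_zero_noise_equals_surface(self, ccd_design, truth):
        from dataclasses import replace

        silent = replace(truth, noise_sd=0.0)
        resp = simulate_doe(ccd_design, silent, seed=0)
        for a in ANALYTES:
            expect = surface_value(truth.surfaces[a], ccd_design.factor_names,
                                   ccd_design.coded)
            assert np.allclose(resp[a], np.clip(expect, 0, 110))

    def test_noise_free_fit_recovers_planted_coefficients(self, ccd_design, truth):
        from dataclasses import replace

        silent = replace(truth, noise_sd=0.0)
        resp = simulate_doe(ccd_design, silent, seed=0)
        model = fit_quadratic(ccd_design, resp["carbendazim"].to_numpy())
        c = truth.surfaces["carbendazim"]
        assert model.coef["intercept"] == pytest.approx(c["b0"], abs=1e-8)
        assert model.coef["gcb"] == pytest.approx(c["gcb"], abs=1e-8)
        assert model.coef["toluene^2"] == pytest.approx(c["toluene^2"], abs=1e-8)

    def test_screening_recovers_planted_factor_set(self):
        """Planted significant factors found (and nulls mostly not) across
        seeds; the smallest planted effect has effect/noise >= 6."""
        n_seeds = 150
        hits = 0
        false_pos = 0
        for s in range(n_seeds):
            truth = make_default_truth(s)
            _, _, tables = pipeline.run_screening(truth, seed=s)
            sig_any = {
                f: any(bool(t.table.loc[f, "significant"]) for t in tables.values())
                for f in ("toluene", "hcl", "gcb", "psa", "c18")
            }
            hits += sig_any["toluene"] and sig_any["hcl"] and sig_any["gcb"]
            false_pos += sig_any["psa"] + sig_any["c18"]
        assert hits / n_seeds >= 0.95
        # per-factor union over 5 analytes: expected ~1-0.95^5 ~ 0.23
        assert false_pos / (2 * n_seeds) < 0.4


class TestSimulateCalibration:
    def test_zero_cv_perfect_line(self, truth):
        from dataclasses import replace

        silent = replace(truth, calibration_cv=0.0)
        tab = simulate_calibration(silent, "carbendazim", "citrus", "ND", seed=0)
        curve = fit_calibration(tab["level_ugL"], tab["signal"])
        assert curve.r_squared == pytest.approx(1.0)

    def test_planted_me_recovered_exactly_without_noise(self, truth):
        from dataclasses import replace

        silent = replace(truth, calibration_cv=0.0)
        for matrix in ("citrus", "lychee"):
            mat = simulate_calibration(silent, "iprodione", matrix, "ND", seed=0)
            sol = simulate_calibration(silent, "iprodione", "methanol", "ND", seed=0)
            me = matrix_effect(fit_calibration(mat["level_ugL"], mat["signal"]),
                               fit_calibration(sol["level_ugL"], sol["signal"]))
            planted = (truth.me_factor[matrix] - 1.0) * 100.0
            assert me.me_percent == pytest.approx(planted, abs=1e-8)

    def test_dilution_shrinks_matrix_effect(self, truth):
        for matrix in truth.me_factor:
            nd = truth.me_factor_for(matrix, "ND")
            d10 = truth.me_factor_for(matrix, "D10")
            if nd != 1.0:
                assert abs(d10 - 1.0) < abs(nd - 1.0)


class TestSimulateRecovery:
    def test_zero_variance_components(self, truth):
        from dataclasses import replace

        silent = replace(truth, recovery_sd_within=0.0, recovery_sd_between=0.0)
        tab = simulate_recovery(silent, "prochloraz", "citrus", "LOQ", seed=0)
        res = recovery_summary(tab)
        assert res.rsd_intra == 0.0
        assert res.rsd_inter == 0.0
        assert res.mean_recovery == pytest.approx(85.0)

    def test_structure(self, truth):
        tab = simulate_recovery(truth, "2,4-D", "apple", "10xLOQ", seed=1)
        assert len(tab) == 15
        assert sorted(tab["day"].unique()) == [1, 2, 3]

    def test_interday_variance_components(self, truth):
        """Observed inter-day variance ~ sigma_between^2 + sigma_within^2."""
        n_mc = 800
        variances = np.empty(n_mc)
        for s in range(n_mc):
            tab = simulate_recovery(truth, "carbendazim", "citrus", "LOQ", seed=s)
            variances[s] = tab["recovery_pct"].var(ddof=1)
        expected = truth.recovery_sd_between**2 + truth.recovery_sd_within**2
        assert variances.mean() == pytest.approx(expected, rel=0.10)

    def test_mean_recovery_unbiased(self, truth):
        n_mc = 300
        means = [recovery_summary(
            simulate_recovery(truth, "iprodione", "mango", "LOQ", seed=s)
        ).mean_recovery for s in range(n_mc)]
        assert np.mean(means) == pytest.approx(85.0, abs=1.0)


class TestSimulateSurvey:
    COUNTS = {c: n for c, n in zip(
        COMMODITIES, (20, 10, 10, 20, 5, 5, 10, 5))}

    def test_zero_prevalence(self, truth):
        from dataclasses import replace

        clean = replace(truth, prevalence=0.0)
        rec = simulate_survey(clean, self.COUNTS, seed=0)
        assert rec["conc_ugkg"].notna().sum() == 0

    def test_full_prevalence_above_loq(self, truth):
        from dataclasses import replace

        hot = replace(truth, prevalence=1.0, survey_log_mu=np.log(100.0),
                      survey_log_sigma=0.1)
        rec = simulate_survey(hot, self.COUNTS, seed=0)
        from quechemo import datasets, validation

        out = validation.survey_summary(rec, datasets.LOQS, self.COUNTS)
        assert out["positive_pct"] == 100

    def test_binomial_mean_positive_rate(self, truth):
        """Uniform prevalence 0.12: mean positive ratio over many surveys is
        within half a point of 12% (censoring kept negligible)."""
        from dataclasses import replace

        spec = replace(truth, prevalence=0.12, survey_log_mu=np.log(50.0),
                       survey_log_sigma=0.3)
        n_mc = 4000
        rates = np.empty(n_mc)
        for s in range(n_mc):
            rec = simulate_survey(spec, self.COUNTS, seed=s)
            rates[s] = 100.0 * rec["conc_ugkg"].notna().sum() / 85.0
        assert rates.mean() == pytest.approx(12.0, abs=0.5)

    def test_determinism(self, truth):
        a = simulate_survey(truth, self.COUNTS, seed=3)
        b = simulate_survey(truth, self.COUNTS, seed=3)
        pd.testing.assert_frame_equal(a, b)
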