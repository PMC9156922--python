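"""Design coding, mixed-model fitting, prediction and per-speed summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rspgait import asymstats, reference
from rspgait.asymstats import (
    TERMS,
    CoefTable,
    LmmSpec,
    build_design,
    build_design_row,
    fit_lmm,
    predict,
    summarize_by_speed,
)
from rspgait.synthgrf import LmmSimConfig, simulate_trial_table


class TestBuildDesign:
    def test_reference_cell_is_all_zero_dummies(self):
        row = build_design_row("Catapult", "-1", 0.0, 3.0)
        assert row["intercept"] == 1.0
        assert row["speed [m s^-1]"] == 3.0
        assert all(
            row[t] == 0.0 for t in TERMS if t not in ("intercept", "speed [m s^-1]")
        )

    def test_full_coding_arithmetic(self):
        row = build_design_row("Xtend", "+1", -2.0, 7.0)
        assert row["model [Xtend]"] == 1.0
        assert row["model [Sprinter]"] == 0.0
        assert row["stiffness cat [+1]"] == 1.0
        assert row["height [cm]"] == -2.0
        assert row["model [Xtend]*speed [m s^-1]"] == 7.0
        assert row["stiffness cat [+1]*speed [m s^-1]"] == 7.0
        assert row["height [cm]*speed [m s^-1]"] == -14.0

    def test_non_integer_height_passes_through(self):
        """Subjects whose residual limb limited the height change used e.g. -1.3 cm."""
        assert build_design_row("Catapult", "-1", -1.3, 3.0)["height [cm]"] == -1.3

    def test_unseen_levels_rejected_by_name(self):
        df = pd.DataFrame(
            {
                "rsp_model": ["Cheetah"],
                "stiffness_cat": ["-1"],
                "height_offset_cm": [0.0],
                "speed_mps": [3.0],
            }
        )
        with pytest.raises(ValueError, match="Cheetah"):
            build_design(df)
        with pytest.raises(ValueError, match="'\\+2'"):
            build_design_row("Catapult", "+2", 0.0, 3.0)

    def test_column_order_matches_reporting_order(self, balanced_design):
        assert list(build_design(balanced_design).columns) == list(TERMS)


def _simulate(coeffs, subject_sd=0.0, residual_sd=0.0, seed=0, design=None):
    cfg = LmmSimConfig(
        coefficients={"al_contact_length_m": coeffs},
        subject_sd={"al_contact_length_m": subject_sd},
        residual_sd={"al_contact_length_m": residual_sd},
        seed=seed,
        design=design,
    )
    return simulate_trial_table(cfg)


class TestFitLmm:
    def test_noise_free_zero_slopes_recovered_exactly(self):
        tab = _simulate({"intercept": 0.5})
        fit = fit_lmm(tab, LmmSpec("al_contact_length_m"))
        assert fit.estimate("intercept") == pytest.approx(0.5, abs=1e-8)
        non_intercept = fit.table.loc[fit.table["term"] != "intercept", "estimate"]
        assert np.abs(non_intercept).max() < 1e-8

    def test_balanced_no_random_effect_matches_ols(self, balanced_design):
        """With subject_sd=0 on a balanced design, fixed effects equal OLS to 1e-6."""
        tab = _simulate(
            {"intercept": 0.53, "speed [m s^-1]": 0.066, "model [Xtend]": -0.037},
            residual_sd=0.02,
            seed=21,
            design=balanced_design,
        )
        fit = fit_lmm(tab, LmmSpec("al_contact_length_m"))
        X = build_design(tab)
        ols = sm.OLS(tab["al_contact_length_m"].to_numpy(), X).fit()
        assert np.abs(fit.table["estimate"].to_numpy() - ols.params.to_numpy()).max() < 1e-6

    def test_reference_level_reparameterization_contrast(self, balanced_design):
        """Refitting with Xtend as reference shifts model terms by the printed contrast."""
        tab = _simulate(
            {"intercept": 0.53, "model [Sprinter]": 0.01, "model [Xtend]": -0.037,
             "speed [m s^-1]": 0.066},
            subject_sd=0.02,
            residual_sd=0.02,
            seed=8,
            design=balanced_design,
        )
        fit = fit_lmm(tab, LmmSpec("al_contact_length_m"))
        relabel = {"Xtend": "Catapult", "Catapult": "Xtend", "Sprinter": "Sprinter"}
        tab2 = tab.assign(rsp_model=tab["rsp_model"].map(relabel))
        fit2 = fit_lmm(tab2, LmmSpec("al_contact_length_m"))
        # "Xtend" dummy in the relabelled fit is the original Catapult-vs-Xtend contrast
        assert fit2.estimate("model [Xtend]") == pytest.approx(
            -fit.estimate("model [Xtend]"), abs=1e-8
        )
        assert fit2.estimate("model [Sprinter]") == pytest.approx(
            fit.estimate("model [Sprinter]") - fit.estimate("model [Xtend]"), abs=1e-8
        )

    def test_predict_reproduces_cell_means_on_noise_free_design(self, balanced_design):
        truth = {"intercept": 0.5, "model [Sprinter]": 0.02, "speed [m s^-1]": 0.07,
                 "height [cm]*speed [m s^-1]": -0.001}
        tab = _simulate(truth, design=balanced_design)
        fit = fit_lmm(tab, LmmSpec("al_contact_length_m"))
        for _, row in tab.head(20).iterrows():
            assert predict(fit, row) == pytest.approx(row["al_contact_length_m"], abs=1e-8)

    def test_rank_deficient_design_rejected(self, balanced_design):
        one_model = balanced_design[balanced_design["rsp_model"] == "Catapult"]
        tab = _simulate({"intercept": 0.5}, residual_sd=0.01, design=one_model)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lmm(tab, LmmSpec("al_contact_length_m"))

    def test_two_subject_minimum(self, balanced_design):
        solo = balanced_design[balanced_design["subject"] == 1]
        tab = _simulate({"intercept": 0.5}, residual_sd=0.01, design=solo)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_lmm(tab, LmmSpec("al_contact_length_m"))


class TestPredict:
    def test_intercept_only_table(self):
        coefs = CoefTable(
            "x", pd.DataFrame({"term": ["intercept"], "estimate": [1.23]})
        )
        out = predict(coefs, dict(rsp_model="Sprinter", stiffness_cat="Rec",
                                  height_offset_cm=2.0, speed_mps=5.0))
        assert out == 1.23

    def test_speed_slope_difference(self):
        coefs = CoefTable(
            "x",
            pd.DataFrame(
                {"term": ["intercept", "speed [m s^-1]"], "estimate": [1.0, 0.25]}
            ),
        )
        cov = dict(rsp_model="Catapult", stiffness_cat="-1", height_offset_cm=0.0)
        d = predict(coefs, {**cov, "speed_mps": 6.0}) - predict(
            coefs, {**cov, "speed_mps": 4.0}
        )
        assert d == pytest.approx(0.25 * 2.0)

    def test_published_contact_length_at_reference_cell(self):
        """Printed coefficients: 0.53 + 0.066 * 3 = 0.728 m at 3 m/s, reference config."""
        coefs = CoefTable(
            "al_contact_length_m", reference.reference_coefficients("al_contact_length_m")
        )
        out = predict(coefs, dict(rsp_model="Catapult", stiffness_cat="-1",
                                  height_offset_cm=0.0, speed_mps=3.0))
        assert out == pytest.approx(0.728, abs=1e-12)

    def test_unknown_term_in_table_rejected(self):
        coefs = CoefTable("x", pd.DataFrame({"term": ["wat"], "estimate": [1.0]}))
        with pytest.raises(KeyError, match="wat"):
            predict(coefs, dict(rsp_model="Catapult", stiffness_cat="-1",
                                height_offset_cm=0.0, speed_mps=3.0))


class TestSummaries:
    def _rows(self, speeds, al_lc):
        n = len(speeds)
        return pd.DataFrame(
            {
                "speed_mps": speeds,
                "al_contact_length_m": al_lc,
                "si_fstep_pct": np.zeros(n),
            }
        )

    def test_per_speed_mean(self):
        out = summarize_by_speed(self._rows([3.0, 3.0], [0.66, 0.68]))
        assert len(out) == 1
        assert out.loc[0, "al_contact_length_m"] == pytest.approx(0.67)
        assert out.loc[0, "n"] == 2

    def test_single_row_summary_is_that_row(self):
        out = summarize_by_speed(self._rows([5.0], [0.8]))
        assert out.loc[0, "al_contact_length_m"] == pytest.approx(0.8)

    def test_empty_speed_cells_omitted(self):
        out = summarize_by_speed(self._rows([3.0, 4.0], [0.6, 0.7]))
        assert list(out["speed_mps"]) == [3.0, 4.0]

    def test_comparison_report_covers_all_terms(self):
        fits = {
            r: CoefTable(r, reference.reference_coefficients(r))
            for r in asymstats.RESPONSES
        }
        report = asymstats.compare_to_reference(fits)
        assert len(report) == 6 * 12
        assert np.allclose(report["difference"], 0.0)
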