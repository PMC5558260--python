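import numpy as np
import pandas as pd
import pytest

from tesdose import stats
from tesdose.stats import (MeasurementTableError, assemble_measurements,
                           cell_mean_contrasts, cross_site_correlation,
                           fit_mixed_model, qq_diagnostics, summarize_cells)

CONFIG_EFFECTS = {"ring": 0.0, "bi_cranial": np.log(2.8),
                  "non_cephalic": np.log(9.7)}


def simulate_table(n_female=6, n_male=6, sex_effect=np.log(2.0),
                   site_effect=0.16, subject_sd=0.5, resid_sd=0.2,
                   seed=0):
    """Forward-style dose table: log-linear effects + subject intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for sex, n in (("female", n_female), ("male", n_male)):
        for _ in range(n):
            re = rng.normal(0.0, subject_sd)
            for cfg, cfg_eff in CONFIG_EFFECTS.items():
                for site, site_eff in (("C3", 0.0), ("F3", site_effect)):
                    base = (1.0 + re + cfg_eff + site_eff
                            + (sex_effect if sex == "male" else 0.0)
                            + rng.normal(0.0, resid_sd))
                    for intensity in (0.5, 1.0, 2.0):
                        rows.append({
                            "subject_id": f"S{sid:03d}", "sex": sex,
                            "configuration": cfg, "site": site,
                            "intensity_mA": intensity,
                            "dose_uA_cm2": float(
                                np.exp(base + np.log(intensity / 0.5)))})
            sid += 1
    return assemble_measurements(rows)


class TestAssemble:
    def test_23_subjects_gives_414_rows(self):
        table = simulate_table(n_female=11, n_male=12, seed=1)
        assert len(table) == 23 * 18

    def test_log_column(self):
        table = simulate_table(seed=2)
        assert np.allclose(table["log_dose"],
                           np.log(table["dose_uA_cm2"]))

    def test_nonpositive_dose_rejected(self):
        table = simulate_table(seed=3)
        table.loc[0, "dose_uA_cm2"] = 0.0
        with pytest.raises(MeasurementTableError, match="non-positive"):
            assemble_measurements(table.drop(columns="log_dose"))

    def test_missing_cell_reported(self):
        table = simulate_table(seed=4).drop(columns="log_dose")
        dropped = table.drop(index=0)
        with pytest.raises(MeasurementTableError, match="S000"):
            assemble_measurements(dropped)


class TestMixedModel:
    def test_intensity_coefficients_exact_on_forward_data(self):
        # solver linearity forces doses proportional to intensity, so the
        # intensity coefficients are exactly ln 2 and ln 4
        table = simulate_table(seed=5)
        fit = fit_mixed_model(table)
        assert fit.terms.loc["intensity[1.0]", "coef"] == \
            pytest.approx(np.log(2.0), abs=1e-8)
        assert fit.terms.loc["intensity[2.0]", "coef"] == \
            pytest.approx(np.log(4.0), abs=1e-8)
        assert fit.exp_coef("intensity[2.0]") == pytest.approx(4.0, rel=1e-6)

    def test_cloned_sexes_give_zero_sex_coefficient(self):
        # same subjects relabeled: exchangeability forces the sex term to 0
        table = simulate_table(n_female=4, n_male=0, sex_effect=0.0, seed=6)
        clone = table.copy()
        clone["sex"] = "male"
        clone["subject_id"] = clone["subject_id"] + "_m"
        both = pd.concat([table, clone], ignore_index=True)
        fit = fit_mixed_model(both)
        assert abs(fit.terms.loc["sex[male]", "coef"]) < 1e-8

    def test_balanced_design_oracle(self):
        # fixed effects equal cell-mean contrasts of log dose on the fully
        # crossed balanced design
        table = simulate_table(n_female=5, n_male=5, seed=7)
        fit = fit_mixed_model(table)
        oracle = cell_mean_contrasts(table)
        for term, expected in oracle.items():
            assert fit.terms.loc[term, "coef"] == \
                pytest.approx(expected, abs=1e-8), term

    def test_interaction_terms_present(self):
        table = simulate_table(seed=8)
        fit = fit_mixed_model(table, include_interactions=True)
        names = set(fit.terms.index)
        assert "config[bi_cranial]:site[F3]" in names
        assert "config[non_cephalic]:sex[male]" in names
        assert "site[F3]:sex[male]" in names
        assert len([n for n in names if ":" in n]) == 5

    def test_sex_term_requires_two_subjects_per_sex(self):
        table = simulate_table(n_female=1, n_male=3, seed=9)
        with pytest.raises(MeasurementTableError, match="2 subjects"):
            fit_mixed_model(table, include_sex=True)
        fit = fit_mixed_model(table, include_sex="auto")
        assert "sex[male]" not in fit.terms.index

    def test_parameter_recovery_single_cohort(self):
        table = simulate_table(n_female=20, n_male=20,
                               sex_effect=np.log(2.0), subject_sd=0.3,
                               resid_sd=0.1, seed=10)
        fit = fit_mixed_model(table)
        assert fit.terms.loc["sex[male]", "coef"] == \
            pytest.approx(np.log(2.0), abs=0.3)
        lo = fit.terms.loc["sex[male]", "ci_low"]
        hi = fit.terms.loc["sex[male]", "ci_high"]
        assert lo < fit.terms.loc["sex[male]", "coef"] < hi

    def test_variance_components_positive(self):
        fit = fit_mixed_model(simulate_table(seed=11))
        assert fit.subject_variance > 0
        assert fit.residual_variance > 0


class TestCrossSiteCorrelation:
    def test_exact_copy_gives_r_one(self):
        table = simulate_table(site_effect=0.0, resid_sd=0.0, seed=12)
        corr = cross_site_correlation(table)
        assert np.allclose(corr["r"], 1.0)

    def test_affine_invariance(self):
        table = simulate_table(seed=13)
        base = cross_site_correlation(table)
        scaled = table.copy()
        f3 = scaled["site"] == "F3"
        scaled.loc[f3, "dose_uA_cm2"] = scaled.loc[f3, "dose_uA_cm2"] * 3.0 \
            + 1.0
        again = cross_site_correlation(scaled)
        assert np.allclose(base["r"], again["r"])

    def test_independent_sites_give_near_zero_r(self):
        # Monte-Carlo under independence of C3 and F3 subject effects
        rng = np.random.default_rng(14)
        rs = []
        for _ in range(200):
            n = 20
            rows = []
            for s in range(n):
                for site in ("C3", "F3"):
                    dose = float(np.exp(rng.normal(1.0, 0.5)))
                    for cfg in CONFIG_EFFECTS:
                        for intensity in (0.5, 1.0, 2.0):
                            rows.append({"subject_id": f"S{s}", "sex":
                                         "female" if s % 2 else "male",
                                         "configuration": cfg, "site": site,
                                         "intensity_mA": intensity,
                                         "dose_uA_cm2": dose * intensity})
            table = assemble_measurements(rows)
            rs.append(cross_site_correlation(table)["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_subjects(self):
        table = simulate_table(n_female=1, n_male=1, seed=15)
        with pytest.raises(MeasurementTableError, match="3 subjects"):
            cross_site_correlation(table)


class TestSummaries:
    def test_36_sex_stratified_cells(self):
        cells = summarize_cells(simulate_table(seed=16))
        strat = cells[cells["sex"] != "all"]
        assert len(strat) == 2 * 3 * 2 * 3

    def test_overall_mean_is_weighted_mean_of_sex_strata(self):
        table = simulate_table(n_female=4, n_male=8, seed=17)
        cells = summarize_cells(table)
        key = ["configuration", "site", "intensity_mA"]
        overall = cells[cells["sex"] == "all"].set_index(key)
        strat = cells[cells["sex"] != "all"]
        for cell, grp in strat.groupby(key):
            weighted = np.average(grp["mean_dose"], weights=grp["n"])
            assert overall.loc[cell, "mean_dose"] == pytest.approx(weighted)

    def test_single_subject_zero_sd(self):
        table = simulate_table(n_female=1, n_male=0, seed=18)
        cells = summarize_cells(table)
        assert np.allclose(cells["sd_dose"], 0.0)


class TestQQDiagnostics:
    def test_standard_normal_residuals_slope_one(self):
        # Monte-Carlo: lognormal doses whose log-residuals are exactly normal
        rng = np.random.default_rng(19)
        rows = []
        for s in range(30):
            for cfg in CONFIG_EFFECTS:
                for site in ("C3", "F3"):
                    for intensity in (0.5, 1.0, 2.0):
                        rows.append({"subject_id": f"S{s}",
                                     "sex": "female" if s % 2 else "male",
                                     "configuration": cfg, "site": site,
                                     "intensity_mA": intensity,
                                     "dose_uA_cm2":
                                     float(np.exp(rng.normal(2.0, 1.0)))})
        qq = qq_diagnostics(assemble_measurements(rows))
        pairs = qq["log"]
        slope, intercept = np.polyfit(pairs["theoretical"],
                                      pairs["observed"], 1)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert intercept == pytest.approx(0.0, abs=0.1)

    def test_log_straightens_lognormal_data(self):
        qq = qq_diagnostics(simulate_table(n_female=15, n_male=15,
                                           subject_sd=0.0, resid_sd=0.8,
                                           seed=20))
        def max_dev(df):
            return np.abs(df["observed"] - df["theoretical"]).max()

        assert max_dev(qq["log"]) < max_dev(qq["raw"])

    def test_identical_values_identical_pairs(self):
        table = simulate_table(seed=21)
        a = qq_diagnostics(table)
        b = qq_diagnostics(table)
        for k in a:
            pd.testing.assert_frame_equal(a[k], b[k])
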