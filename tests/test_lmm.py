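import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import patsy
import pytest
import statsmodels.formula.api as smf

from affectbias import synth
from affectbias._typeii import type2_wald_table
from affectbias.lmm import (BiasMixedModel, per_cohort_refits,
                            run_model_selection, stim_control_model, wald_type2)


def _sim_frame(seed=42, n=120):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "bias": rng.normal(0, 0.1, n),
        "valence": rng.choice(["happy", "sad"], n),
        "iclass": rng.choice(["subtle", "overt"], n),
        "week": rng.uniform(0, 24, n),
        "subject": rng.choice([f"s{i}" for i in range(8)], n),
    })
    u = dict(zip([f"s{i}" for i in range(8)], rng.normal(0, 2, 8)))
    df["hdrs"] = (22 - 6 * df.bias - 0.2 * df.week + 1.5 * (df.valence == "happy")
                  - 3 * df.bias * (df.valence == "happy")
                  + df.subject.map(u) + rng.normal(0, 1, n))
    return df


class TestTypeIIWald:
    def test_single_coefficient_is_squared_z(self):
        # a lone continuous predictor with estimate 2 and SE 1 gives chi2 = 4
        di = patsy.dmatrix("x", {"x": [0.0, 1.0, 2.0]}).design_info
        tab = type2_wald_table(np.array([0.0, 2.0]), np.eye(2), di)
        assert tab.loc[0, "chisq"] == pytest.approx(4.0, abs=1e-12)
        assert tab.loc[0, "df"] == 1

    def test_zero_coefficient_gives_p_one(self):
        di = patsy.dmatrix("x", {"x": [0.0, 1.0, 2.0]}).design_info
        tab = type2_wald_table(np.array([3.0, 0.0]), np.eye(2), di)
        assert tab.loc[0, "chisq"] == 0.0 and tab.loc[0, "p"] == 1.0

    def test_terms_without_relatives_equal_marginal_wald(self):
        """In a model with no interactions every Type II test collapses to
        the marginal Wald test of that term's coefficients."""
        df = _sim_frame()
        ols = smf.ols("hdrs ~ bias + C(valence, Sum) + week", df).fit()
        tab = wald_type2(ols).set_index("term")
        for name, col in [("bias", "bias"), ("week", "week")]:
            z2 = (ols.params[col] / ols.bse[col]) ** 2
            assert tab.loc[name, "chisq"] == pytest.approx(z2, abs=1e-8)

    def test_units_invariance(self):
        df = _sim_frame()
        a = wald_type2(smf.ols("hdrs ~ bias * C(valence, Sum) + week", df).fit())
        df2 = df.assign(bias=df.bias * 37.0)
        b = wald_type2(smf.ols("hdrs ~ bias * C(valence, Sum) + week", df2).fit())
        np.testing.assert_allclose(a["chisq"], b["chisq"], rtol=1e-9)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_car_anova(self, tmp_path):
        """Independent oracle: car::Anova type II on the identical data, for
        both an OLS fit (exact agreement) and a REML lmer fit (optimizer-level
        agreement)."""
        df = _sim_frame()
        csv = tmp_path / "d.csv"
        out = tmp_path / "r.json"
        df.to_csv(csv, index=False)
        rcode = f"""
        options(contrasts = c("contr.sum", "contr.poly"))
        suppressMessages({{library(car); library(lme4); library(jsonlite)}})
        d <- read.csv("{csv}")
        m <- lm(hdrs ~ bias * valence + week + iclass, d)
        a <- Anova(m, type = "II", test.statistic = "F")
        ml <- lmer(hdrs ~ bias * valence + week + iclass + (1 | subject), d, REML = TRUE)
        al <- Anova(ml, type = "II")
        res <- list(ols = setNames(as.list(a[["F value"]]), rownames(a)),
                    lmm = setNames(as.list(al[["Chisq"]]), rownames(al)))
        write(toJSON(res, auto_unbox = TRUE, digits = 12), "{out}")
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        r = json.loads(out.read_text())

        name_map = {"bias": "bias", "valence": "valence", "week": "week",
                    "iclass": "iclass", "bias:valence": "bias:valence"}
        ols_tab = wald_type2(
            smf.ols("hdrs ~ bias * C(valence, Sum) + week + C(iclass, Sum)", df).fit()
        ).set_index("term")
        for rname, pname in name_map.items():
            # with df1 = 1 the F statistic equals the Wald chi-square exactly
            assert ols_tab.loc[pname, "chisq"] == pytest.approx(
                r["ols"][rname], rel=1e-6), pname

        from affectbias.lmm import _fit_mixedlm
        res = _fit_mixedlm(
            "hdrs ~ bias * C(valence, Sum) + week + C(iclass, Sum)", df, "subject")
        lmm_tab = wald_type2(res).set_index("term")
        for rname, pname in name_map.items():
            assert lmm_tab.loc[pname, "chisq"] == pytest.approx(
                r["lmm"][rname], rel=1e-2), pname


class TestBiasMixedModel:
    def test_fit_reports_components_and_anova(self):
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(1))
        m = BiasMixedModel(cohort_re=False).fit(cells)
        assert m.converged_
        assert set(m.anova_["term"]) == {
            "mean_bias", "valence", "mean_bias:valence", "week", "intensity_class"}
        assert (m.anova_["df"] == 1).all()
        assert m.var_components_["subject"] > 0
        assert m.cov_fe_.shape[0] == len(m.fe_params_)
        # covariance is symmetric PSD
        c = m.cov_fe_.to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() > -1e-10

    def test_boundary_cohort_variance_flagged_singular(self):
        # seed chosen arbitrarily among null-cohort datasets; the generator
        # puts no cohort effect in, so the variance sits at the boundary
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(9000))
        m = BiasMixedModel(cohort_re=True).fit(cells)
        assert m.singular_dropped_ == ["cohort"]
        assert "cohort" not in m.var_components_

    def test_genuine_cohort_variance_retained(self):
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(9000))
        cells = cells.copy()
        cells.loc[cells["cohort"] == "B", "hdrs17"] += 12.0
        m = BiasMixedModel(cohort_re=True).fit(cells)
        assert m.singular_dropped_ == []
        assert m.var_components_["cohort"] > 1.0

    def test_single_subject_random_intercept_rejected(self):
        cells, _ = synth.gen_cells_direct(
            synth.DirectCellConfig(n_monthly=1, n_biweekly=0), np.random.default_rng(0))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            BiasMixedModel().fit(cells)

    def test_missing_values_rejected(self):
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(2))
        cells.loc[cells.index[0], "hdrs17"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            BiasMixedModel().fit(cells)

    def test_predict_is_fixed_effects_only(self):
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(3))
        m = BiasMixedModel(cohort_re=False).fit(cells)
        pred = m.predict(cells)
        X = patsy.build_design_matrices(
            [m.result_.model.data.design_info], cells)[0]
        np.testing.assert_allclose(pred, np.asarray(X) @ m.fe_params_.to_numpy(),
                                   rtol=1e-10)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        m = BiasMixedModel(include_initial=True, singular_tol=0.02)
        m2 = clone(m)
        assert m2.include_initial and m2.singular_tol == 0.02


class TestModelSelection:
    def test_iteration2_triggered_when_initial_uninformative(self):
        fired = 0
        for r in range(10):
            cells, _ = synth.gen_cells_direct(
                synth.DirectCellConfig(initial_coef=0.0), np.random.default_rng(800 + r))
            sel = run_model_selection(cells)
            fired += sel.iteration2 is not None
        assert fired >= 8

    def test_iteration1_retained_under_strong_initial_effect(self):
        kept = 0
        for r in range(10):
            cells, _ = synth.gen_cells_direct(
                synth.DirectCellConfig(initial_coef=0.8, resid_sd=0.8, subject_sd=0.5),
                np.random.default_rng(900 + r))
            sel = run_model_selection(cells)
            kept += sel.iteration2 is None
        assert kept >= 8

    def test_subjects_missing_initial_excluded_from_iteration1(self, cells):
        sel = run_model_selection(cells)
        n_all = cells["subject_id"].nunique()
        assert any("missing initial" in t for t in sel.trail)
        # iteration 1 used one subject fewer than the full table
        n_it1 = cells.loc[cells["initial_hdrs17"].notna(), "subject_id"].nunique()
        assert n_it1 == n_all - 1


class TestPerCohort:
    def test_identical_cohorts_identical_tables(self):
        cells, _ = synth.gen_cells_direct(
            synth.DirectCellConfig(n_monthly=4, n_biweekly=0), np.random.default_rng(5))
        mirror = cells.copy()
        mirror["cohort"] = "B"
        mirror["subject_id"] = mirror["subject_id"].str.replace("E", "B")
        both = pd.concat([cells, mirror], ignore_index=True)
        fits = per_cohort_refits(both)
        np.testing.assert_allclose(fits["E"].anova_["chisq"],
                                   fits["B"].anova_["chisq"], rtol=1e-6)

    def test_empty_cohort_errors(self):
        cells, _ = synth.gen_cells_direct(
            synth.DirectCellConfig(n_biweekly=0), np.random.default_rng(6))
        with pytest.raises(ValueError, match="'B'"):
            per_cohort_refits(cells)

    def test_two_subject_cohort_keeps_intercept_with_warning(self):
        cells, _ = synth.gen_cells_direct(synth.DirectCellConfig(),
                                          np.random.default_rng(7))
        with pytest.warns(UserWarning, match="only 2 subjects"):
            fits = per_cohort_refits(cells)
        assert "subject" in fits["B"].var_components_

    def test_single_subject_cohort_drops_intercept(self):
        cells, _ = synth.gen_cells_direct(
            synth.DirectCellConfig(n_biweekly=1), np.random.default_rng(8))
        with pytest.warns(UserWarning, match="random"):
            fits = per_cohort_refits(cells)
        assert "subject" not in fits["B"].var_components_


class TestStimGate:
    def test_balanced_blocks_and_gate_fields(self, scored):
        gate = stim_control_model(scored.loc[scored["cohort"] == "E"])
        assert gate.n_blocks_on == gate.n_blocks_off
        assert 0 <= gate.stim_p <= 1
        assert gate.exclude_stimulation == (gate.stim_p > 0.05)

    def test_stim_coding_invariance(self, scored):
        e_style = scored.loc[scored["cohort"] == "E"]
        a = stim_control_model(e_style)
        flipped = e_style.copy()
        flipped["stim_on"] = ~flipped["stim_on"]
        b = stim_control_model(flipped)
        assert a.stim_p == pytest.approx(b.stim_p, rel=1e-6)

    def test_single_state_rejected(self, scored):
        on_only = scored.loc[scored["stim_on"]]
        with pytest.raises(ValueError, match="stimulation state"):
            stim_control_model(on_only)
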