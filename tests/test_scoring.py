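import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectbias import synth
from affectbias.scoring import (aggregate_bias, build_cells, intensity_class,
                                score_trials, select_prepost)


def _mini_scores(biases, valences):
    return pd.DataFrame({"bias": biases, "valence": valences})


class TestScoreTrials:
    def test_definitional_subtraction(self, norm_ref, study_dataset):
        trials = study_dataset["trials"].head(50).copy()
        trials["rating"] = 0.4
        norms = norm_ref.norms_.copy()
        norms["expected_score"] = 0.5
        out = score_trials(trials, norms)
        np.testing.assert_allclose(out["bias"], -0.1, atol=1e-15)

    def test_observed_equal_expected_gives_zero(self, norm_ref, study_dataset):
        trials = study_dataset["trials"].head(50).copy()
        lut = norm_ref.norms_.set_index(["identity", "valence", "intensity"])
        keys = pd.MultiIndex.from_frame(trials[["identity", "valence", "intensity"]])
        trials["rating"] = lut.loc[keys, "expected_score"].to_numpy()
        out = score_trials(trials, norm_ref.norms_)
        np.testing.assert_allclose(out["bias"], 0.0, atol=1e-15)

    def test_injected_shift_recovered(self, norm_ref):
        """A -0.08 shift injected on happy trials shows up as a ~-0.08 mean
        positive-valence bias (within Monte-Carlo and norm-estimation error)."""
        cfg = synth.GeneratorConfig(initial_bias=-0.04, subject_bias_sd=0.0,
                                    visit_bias_sd=0.0, valence_asymmetry=1.0,
                                    bias_tau_weeks=1e9, subject_offset_sd=0.0)
        # asymmetry 1 puts 2 x B0 = -0.08 on happy trials, none on sad
        trials, _, _ = synth.gen_patients(cfg, np.random.default_rng(4))
        scored = norm_ref.transform(trials)
        pos_mean, _ = aggregate_bias(scored, "positive")
        neg_mean, _ = aggregate_bias(scored, "negative")
        assert pos_mean == pytest.approx(-0.08, abs=0.01)
        assert neg_mean == pytest.approx(0.0, abs=0.01)

    @given(delta=st.floats(-0.2, 0.2, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_constant_shift_moves_every_bias_by_delta(self, delta):
        ref_trials = getattr(self, "_cache", None)
        if ref_trials is None:
            data = synth.generate_dataset(synth.GeneratorConfig(n_monthly=1, n_biweekly=0),
                                          seed=11)
            from affectbias.normative import NormativeReference
            ref = NormativeReference().fit(data["controls"])
            type(self)._cache = ref_trials = (ref, data["trials"].head(200))
        ref, trials = ref_trials
        base = ref.transform(trials)
        shifted = trials.copy()
        shifted["rating"] = np.clip(shifted["rating"], 0.3, 0.7) + delta
        base2 = trials.copy()
        base2["rating"] = np.clip(base2["rating"], 0.3, 0.7)
        np.testing.assert_allclose(
            ref.transform(shifted)["bias"] - ref.transform(base2)["bias"],
            delta, atol=1e-12)


class TestAggregateBias:
    def test_positive_retains_only_happy(self):
        s = _mini_scores([0.1] * 24 + [0.0] * 6, ["happy"] * 24 + ["neutral"] * 6)
        mean, kept = aggregate_bias(s, "positive")
        assert len(kept) == 24 and mean == pytest.approx(0.1)

    def test_total_excludes_neutral_hand_case(self):
        s = _mini_scores([0.1, -0.3, 0.0, 0.2], ["happy", "sad", "neutral", "happy"])
        mean, kept = aggregate_bias(s, "total")
        assert len(kept) == 3
        assert mean == pytest.approx((0.1 - 0.3 + 0.2) / 3)
        assert mean == pytest.approx(0.0, abs=1e-15)

    def test_zero_biases_zero_mean_everywhere(self):
        s = _mini_scores([0.0] * 6, ["happy", "sad", "happy", "sad", "happy", "sad"])
        for agg in ("total", "positive", "negative"):
            assert aggregate_bias(s, agg)[0] == 0.0

    def test_empty_aggregation_errors(self):
        s = _mini_scores([0.1], ["happy"])
        with pytest.raises(ValueError, match="retained no trials"):
            aggregate_bias(s, "negative")

    def test_total_is_count_weighted_mean_of_valences(self, scored):
        tot, ktot = aggregate_bias(scored, "total")
        pos, kpos = aggregate_bias(scored, "positive")
        neg, kneg = aggregate_bias(scored, "negative")
        assert len(kpos) + len(kneg) == len(ktot)
        assert tot == pytest.approx(
            (pos * len(kpos) + neg * len(kneg)) / len(ktot), abs=1e-12)


class TestBuildCells:
    def test_intensity_classes_partition_levels(self):
        out = intensity_class(pd.Series([10, 30, 50, 100, 0]))
        assert list(out[:4]) == ["subtle", "subtle", "overt", "overt"]
        assert pd.isna(out[4])

    def test_one_e_style_session_gives_four_cells_of_24(self, norm_ref):
        cfg = synth.GeneratorConfig(n_monthly=1, n_biweekly=0, monthly_weeks=(4.0,))
        trials, clinical, _ = synth.gen_patients(cfg, np.random.default_rng(0))
        scored = norm_ref.transform(trials)
        cells = build_cells(scored, clinical)
        assert len(cells) == 4
        assert (cells["n_trials"] == 24).all()
        assert set(map(tuple, cells[["valence", "intensity_class"]].values)) == {
            ("happy", "subtle"), ("happy", "overt"),
            ("sad", "subtle"), ("sad", "overt")}

    def test_session_without_hdrs_dropped(self, norm_ref):
        cfg = synth.GeneratorConfig(n_monthly=1, n_biweekly=0, monthly_weeks=(4.0, 8.0))
        trials, clinical, _ = synth.gen_patients(cfg, np.random.default_rng(0))
        scored = norm_ref.transform(trials)
        cells = build_cells(scored, clinical.iloc[:1])
        assert len(cells) == 4  # only the matched session remains

    def test_cell_trial_counts_reconcile_with_input(self, scored, cells, study_dataset):
        matched = scored.loc[scored["valence"] != "neutral"].merge(
            study_dataset["clinical"].rename(columns={"date": "session_date"}),
            on=["subject_id", "session_date"], how="inner")
        assert cells["n_trials"].sum() == len(matched)

    def test_mean_bias_is_arithmetic_mean_of_members(self, scored, cells):
        row = cells.iloc[0]
        emotional = scored.loc[scored["valence"] != "neutral"].copy()
        emotional["iclass"] = intensity_class(emotional["intensity"]).to_numpy()
        members = emotional.loc[
            (emotional["subject_id"] == row["subject_id"])
            & (emotional["session_date"] == row["session_date"])
            & (emotional["valence"] == row["valence"])
            & (emotional["iclass"] == row["intensity_class"])
        ]
        assert row["mean_bias"] == pytest.approx(members["bias"].mean(), abs=1e-12)


class TestSelectPrepost:
    @staticmethod
    def _trials(weeks_stim):
        rows = []
        for week, stim in weeks_stim:
            for i in range(3):
                rows.append({"subject_id": "s", "session_date": f"d{week:+.0f}",
                             "week": week, "stim_on": stim, "bias": 0.0,
                             "valence": "happy"})
        return pd.DataFrame(rows)

    def test_first_outpatient_before_onset_is_pre(self):
        t = self._trials([(0, False), (4, True), (24, True)])
        sel, pre, post = select_prepost(t)
        assert sel["s"] == ("d+0", "d+24")
        assert set(pre["week"]) == {0} and set(post["week"]) == {24}

    def test_presurgical_fallback_when_first_visit_missing(self):
        t = self._trials([(-1, False), (4, True), (24, True)])
        sel, _, _ = select_prepost(t)
        assert sel["s"] == ("d-1", "d+24")

    def test_single_session_subject_excluded(self):
        t = self._trials([(4, True)])
        sel, pre, post = select_prepost(t)
        assert sel == {} and len(pre) == 0 and len(post) == 0

    def test_no_session_before_onset_excluded(self):
        t = self._trials([(4, True), (24, True)])
        sel, _, _ = select_prepost(t)
        assert sel == {}

    def test_study_shaped_dataset_selects_all_subjects(self, scored):
        sel, pre, post = select_prepost(scored)
        assert len(sel) == 10
        # every pre session precedes its post session
        assert all(p0 < p1 for (p0, p1) in sel.values())
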