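"""Bias-score assembly: trial scoring, aggregation, analysis cells, pre/post.

Works on flat trial tables (one row per rated face presentation) carrying
the stimulus metadata columns of :mod:`affectbias.stimuli` plus ``rating``.
The scored table additionally carries ``expected_score`` and ``bias``
(observed minus norm; negative = rated sadder than controls).

Analysis cells aggregate scored non-neutral trials to one row per
subject x visit x valence x intensity-class, matched to the same-day
HDRS-17 clinical score.  Intensity classes partition the four morph
strengths into subtle = {10, 30}% and overt = {50, 100}%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .normative import FACE_KEY

logger = logging.getLogger(__name__)

__all__ = [
    "score_trials",
    "aggregate_bias",
    "build_cells",
    "select_prepost",
    "intensity_class",
]

SUBTLE = frozenset({10, 30})
OVERT = frozenset({50, 100})


def intensity_class(intensity) -> pd.Series:
    """Map unsigned morph intensity (%) to 'subtle'/'overt' (neutral -> NA)."""
    s = pd.Series(intensity)
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s.isin(SUBTLE)] = "subtle"
    out[s.isin(OVERT)] = "overt"
    return out


def score_trials(trials: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Bias-score each trial against the norm table (order preserved)."""
    lut = norms.set_index(FACE_KEY)["expected_score"]
    keys = pd.MultiIndex.from_frame(trials[FACE_KEY])
    known = keys.isin(lut.index)
    if not known.all():
        raise KeyError(f"face {tuple(keys[~known][0])} has no normative expected score")
    out = trials.copy()
    out["expected_score"] = lut.loc[keys].to_numpy()
    out["bias"] = out["rating"].to_numpy(float) - out["expected_score"].to_numpy(float)
    return out


def aggregate_bias(scores: pd.DataFrame, aggregation: str = "total"):
    """Mean bias over an aggregation of non-neutral trials.

    aggregation: 'total' (happy + sad), 'positive' (happy only) or
    'negative' (sad only); neutral trials never contribute.  Returns
    ``(mean_bias, retained_scores)``.
    """
    masks = {
        "total": scores["valence"] != "neutral",
        "positive": scores["valence"] == "happy",
        "negative": scores["valence"] == "sad",
    }
    if aggregation not in masks:
        raise ValueError(f"aggregation must be one of {sorted(masks)}, got {aggregation!r}")
    kept = scores.loc[masks[aggregation]]
    if len(kept) == 0:
        raise ValueError(f"aggregation {aggregation!r} retained no trials")
    return float(kept["bias"].mean()), kept


def build_cells(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Aggregate scored trials to HDRS-matched analysis cells.

    One output row per subject x session x valence x intensity-class over
    the non-neutral trials, carrying ``mean_bias``, ``n_trials``, the
    same-day ``hdrs17``, the week since implant, cohort, and the fraction
    of member trials collected under active stimulation.  Sessions with no
    same-day HDRS-17 record are dropped (count logged).  ``initial_hdrs17``
    is carried through when the clinical table provides it.
    """
    need = {"subject_id", "date", "hdrs17"}
    if not need.issubset(clinical.columns):
        raise ValueError(f"clinical table needs columns {sorted(need)}")
    clin = clinical.rename(columns={"date": "session_date"})
    keep_cols = ["subject_id", "session_date", "hdrs17"]
    if "initial_hdrs17" in clin.columns:
        keep_cols.append("initial_hdrs17")
    clin = clin[keep_cols].drop_duplicates(["subject_id", "session_date"])

    s = scores.loc[scores["valence"] != "neutral"].copy()
    s["intensity_class"] = intensity_class(s["intensity"]).to_numpy()
    merged = s.merge(clin, on=["subject_id", "session_date"], how="left", validate="m:1")

    unmatched = merged["hdrs17"].isna()
    if unmatched.any():
        n_sess = merged.loc[unmatched, ["subject_id", "session_date"]].drop_duplicates()
        logger.warning(
            "dropped %d session(s) (%d trials) with no same-day HDRS-17",
            len(n_sess), int(unmatched.sum()),
        )
        merged = merged.loc[~unmatched]

    group_cols = ["subject_id", "cohort", "session_date", "week", "valence", "intensity_class"]
    agg = {"bias": ["mean", "size"], "stim_on": "mean", "hdrs17": "first"}
    if "initial_hdrs17" in merged.columns:
        agg["initial_hdrs17"] = "first"
    cells = merged.groupby(group_cols, sort=True, dropna=False).agg(agg)
    cells.columns = [
        {"biasmean": "mean_bias", "biassize": "n_trials", "stim_onmean": "stim_frac",
         "hdrs17first": "hdrs17", "initial_hdrs17first": "initial_hdrs17"}["".join(c)]
        for c in cells.columns
    ]
    cells = cells.reset_index()
    cells["n_trials"] = cells["n_trials"].astype(int)
    return cells


def select_prepost(trials: pd.DataFrame):
    """Select each subject's pre-DBS and post-DBS sessions.

    Stimulation onset for a subject is the earliest session containing any
    stimulation-on trial.  The pre-DBS session is the first outpatient
    visit (week >= 0) preceding onset; when a subject has no outpatient
    session before onset, the session closest in time to the first
    outpatient visit but still preceding onset is used (in practice the
    pre-surgical baseline).  The post-DBS session is the final outpatient
    visit.  Subjects with no session preceding onset, or with fewer than
    two sessions, are excluded with a logged warning.

    Returns ``(selection, pre_trials, post_trials)`` where ``selection``
    maps subject_id to the chosen (pre, post) session dates.
    """
    sess = (
        trials.groupby(["subject_id", "session_date"], sort=True)
        .agg(week=("week", "first"), any_stim=("stim_on", "any"))
        .reset_index()
    )
    selection: dict[str, tuple] = {}
    for subj, g in sess.groupby("subject_id", sort=True):
        g = g.sort_values("week")  # chronological regardless of date labels
        if len(g) < 2:
            logger.warning("subject %s has a single session; excluded from pre/post", subj)
            continue
        onset_rows = g.loc[g["any_stim"]]
        onset = onset_rows["week"].min() if len(onset_rows) else None
        before = g if onset is None else g.loc[g["week"] < onset]
        if len(before) == 0:
            logger.warning("subject %s has no session before stimulation onset; excluded", subj)
            continue
        outpatient = before.loc[before["week"] >= 0]
        if len(outpatient):
            pre = outpatient.iloc[0]["session_date"]
        else:
            # closest in time to the first outpatient visit, still pre-onset
            pre = before.iloc[-1]["session_date"]
        post = g.iloc[-1]["session_date"]
        if post == pre:
            logger.warning("subject %s: pre and post coincide; excluded", subj)
            continue
        selection[subj] = (pre, post)

    def _pick(which: int) -> pd.DataFrame:
        frames = [
            trials.loc[
                (trials["subject_id"] == subj)
                & (trials["session_date"] == dates[which])
            ]
            for subj, dates in selection.items()
        ]
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else trials.iloc[0:0].copy()
        )

    return selection, _pick(0), _pick(1)
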