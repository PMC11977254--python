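"""Normative reference construction from healthy-control ratings.

Controls rate each face exemplar on the same 0 ("Very Sad") to 1 ("Very
Happy") scale as patients.  For each face we compute the mean and sample
standard deviation over all control ratings, exclude ratings lying more
than two standard deviations from that mean (a single trimming pass), and
take the mean of the retained ratings as the face's *expected score*.  A
patient's *bias score* for a trial is then the observed rating minus the
expected score for the same face, so negative bias means "rated sadder
than controls".

`NormativeReference` packages this as a scikit-learn style transformer:
``fit`` consumes a control-rating table and stores the norm table;
``transform`` maps a patient trial table to the same table with
``expected_score`` and ``bias`` columns appended.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

FACE_KEY = ["identity", "valence", "intensity"]

__all__ = ["NormativeReference", "compute_norms", "screen_controls", "FACE_KEY"]


def compute_norms(
    ratings: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-face trimmed-mean expected scores with a trimming audit.

    Parameters
    ----------
    ratings
        Control ratings, one row per (rater, face) with columns
        ``identity, valence, intensity, rating`` (rating in [0, 1]).
    registry
        Optional registry table; when given, every registry face must be
        rated (by at least two raters) and the output carries exactly the
        registry's faces.  When omitted the faces present in ``ratings``
        define the table.
    n_sd
        Trimming threshold in standard deviations (default 2).  Exclusion
        is strict (``|r - m| > n_sd * s``): a rating exactly at the
        threshold is retained.  The standard deviation uses the n-1
        denominator.  Trimming is a single pass: mean and SD are computed
        once on the full set, and the expected score is the mean of the
        retained ratings.

    Returns
    -------
    DataFrame with one row per face: the face key columns plus
    ``signed_intensity, expected_score, raw_mean, raw_sd, n_total,
    n_excluded``.
    """
    missing = [c for c in FACE_KEY + ["rating"] if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    r = ratings["rating"].to_numpy(float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("ratings must lie in [0, 1]")

    if registry is not None:
        faces = registry[FACE_KEY].drop_duplicates()
        have = set(map(tuple, ratings[FACE_KEY].itertuples(index=False)))
        absent = [f for f in map(tuple, faces.itertuples(index=False)) if f not in have]
        if absent:
            raise ValueError(f"no control ratings for face(s): {absent[:5]}")

    rows = []
    for key, grp in ratings.groupby(FACE_KEY, sort=True):
        vals = grp["rating"].to_numpy(float)
        n = vals.size
        if n < 2:
            raise ValueError(
                f"face {dict(zip(FACE_KEY, key))} has {n} control rating(s); need >= 2"
            )
        m = vals.mean()
        s = vals.std(ddof=1)
        if s == 0.0:
            # zero (or underflowed) spread: nothing can be an outlier
            keep = np.ones(n, bool)
        else:
            keep = np.abs(vals - m) <= n_sd * s
        # With n_sd >= 1 the trimming rule cannot exclude every rating.
        assert keep.any(), "trimming excluded all ratings (impossible by construction)"
        expected = vals[keep].mean()
        identity, valence, intensity = key
        sign = {"sad": -1, "neutral": 0, "happy": 1}[valence]
        rows.append(
            {
                "identity": identity,
                "valence": valence,
                "intensity": int(intensity),
                "signed_intensity": sign * int(intensity),
                "expected_score": expected,
                "raw_mean": m,
                "raw_sd": s,
                "n_total": int(n),
                "n_excluded": int(n - keep.sum()),
            }
        )
    return pd.DataFrame(rows)


def screen_controls(
    screen_scores: pd.DataFrame,
    cutoff: float = 0.0,
    score_col: str = "screen_score",
) -> pd.DataFrame:
    """Retain raters whose depression-screen score is at or below cutoff.

    ``screen_scores`` has one row per rater (``rater_id`` plus the score
    column).  Raters with a missing score are dropped with a warning.
    Returns the retained subset of the input table.
    """
    if "rater_id" not in screen_scores.columns or score_col not in screen_scores.columns:
        raise ValueError(f"need columns 'rater_id' and {score_col!r}")
    missing = screen_scores[score_col].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} rater(s) missing a screen score; dropped",
            stacklevel=2,
        )
    ok = screen_scores.loc[~missing]
    return ok.loc[ok[score_col] <= cutoff].copy()


class NormativeReference(BaseEstimator, TransformerMixin):
    """Trimmed-mean normative reference: control ratings in, bias scores out.

    Parameters
    ----------
    n_sd : float, default 2.0
        Trimming threshold for control ratings, in SDs of each face's
        rating distribution.

    Attributes
    ----------
    norms_ : DataFrame
        Per-face norm table (see :func:`compute_norms`).
    n_faces_ : int
        Number of faces in the norm table.
    n_excluded_ : int
        Total control ratings excluded by trimming.
    """

    def __init__(self, n_sd: float = 2.0):
        self.n_sd = n_sd

    def fit(self, X: pd.DataFrame, y=None, registry: pd.DataFrame | None = None):
        self.norms_ = compute_norms(X, registry=registry, n_sd=self.n_sd)
        self.n_faces_ = len(self.norms_)
        self.n_excluded_ = int(self.norms_["n_excluded"].sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append ``expected_score`` and ``bias`` to a patient trial table.

        Every face appearing in ``X`` must be present in the norm table;
        an unknown face is an error naming the face.  Row order is
        preserved.
        """
        if not hasattr(self, "norms_"):
            raise RuntimeError("NormativeReference is not fitted")
        lut = self.norms_.set_index(FACE_KEY)["expected_score"]
        keys = pd.MultiIndex.from_frame(X[FACE_KEY])
        known = keys.isin(lut.index)
        if not known.all():
            bad = keys[~known][0]
            raise KeyError(f"face {tuple(bad)} has no normative expected score")
        out = X.copy()
        out["expected_score"] = lut.loc[keys].to_numpy()
        out["bias"] = out["rating"].to_numpy(float) - out["expected_score"].to_numpy(float)
        return out
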