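"""Leave-one-patient-out cross-validation of HDRS-17 prediction.

Each round refits the final (iteration-2) HDRS~Bias mixed model on all
but one subject and predicts the held-out subject's HDRS-17 from fixed
effects only — the random intercept of an unseen subject is necessarily
zero, which matters for the attainable R^2 and is therefore stated here
rather than left implicit.  Predictions are aggregated to one value per
visit (cells of a visit share the observed HDRS-17) and the per-subject
R^2 is the squared Pearson correlation between predicted and observed
across that subject's visits; the coefficient-of-determination variant
(1 - SSE/SST, unbounded below) is available behind a flag.  A one-sample
t-test then compares the per-subject R^2 values to zero.  Note that
testing nonnegative R^2 values against zero is anti-conservative by
construction; the test is reported as designed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import BiasMixedModel

logger = logging.getLogger(__name__)

__all__ = ["LoocvResult", "loocv"]


@dataclass
class LoocvResult:
    per_subject: pd.DataFrame  # subject_id, r_squared, n_visits
    mean_r2: float
    sd_r2: float
    t_stat: float
    df: int
    p: float
    excluded: list

    def as_dict(self) -> dict:
        return {
            "per_subject": self.per_subject.to_dict(orient="records"),
            "mean_r2": self.mean_r2, "sd_r2": self.sd_r2,
            "t_stat": self.t_stat, "df": self.df, "p": self.p,
            "excluded": list(self.excluded),
        }


def loocv(
    cells: pd.DataFrame,
    include_stim: bool = False,
    min_visits: int = 3,
    r2_kind: str = "pearson",
) -> LoocvResult:
    """Leave-one-subject-out HDRS-17 prediction from bias cells.

    Parameters
    ----------
    cells
        The HDRS-matched cell table (all subjects).
    min_visits
        Subjects with fewer visits are not tested (a correlation over two
        points is vacuous).
    r2_kind
        'pearson' (squared correlation, in [0, 1]) or 'cod'
        (1 - SSE/SST, can be negative).

    Held-out subjects whose observed HDRS-17 is constant across visits
    have an undefined correlation and are excluded with a warning.
    """
    if r2_kind not in ("pearson", "cod"):
        raise ValueError("r2_kind must be 'pearson' or 'cod'")
    subjects = sorted(cells["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")

    rows = []
    excluded = []
    for subj in subjects:
        held = cells.loc[cells["subject_id"] == subj]
        n_visits = held["session_date"].nunique()
        if n_visits < min_visits:
            excluded.append(subj)
            logger.warning("subject %s has %d visit(s) < %d; not tested",
                           subj, n_visits, min_visits)
            continue
        train = cells.loc[cells["subject_id"] != subj]
        # iteration-2 structure: subject intercept only (the cohort intercept
        # is singular on this design and was dropped at model selection)
        model = BiasMixedModel(include_initial=False, include_stim=include_stim,
                               cohort_re=False)
        model.fit(train)
        pred = held.assign(_pred=model.predict(held))
        per_visit = (
            pred.groupby("session_date", sort=True)
            .agg(predicted=("_pred", "mean"), observed=("hdrs17", "first"))
        )
        obs = per_visit["observed"].to_numpy(float)
        est = per_visit["predicted"].to_numpy(float)
        if np.ptp(obs) == 0:
            excluded.append(subj)
            logger.warning("subject %s has constant observed HDRS-17; "
                           "correlation undefined, excluded", subj)
            continue
        if r2_kind == "pearson":
            r2 = float(stats.pearsonr(est, obs).statistic ** 2)
        else:
            sse = float(np.sum((obs - est) ** 2))
            sst = float(np.sum((obs - obs.mean()) ** 2))
            r2 = 1.0 - sse / sst
        rows.append({"subject_id": subj, "r_squared": r2, "n_visits": int(n_visits)})

    per_subject = pd.DataFrame(rows)
    if len(per_subject) < 2:
        raise ValueError("fewer than 2 testable subjects; cannot test R^2 against 0")
    r2s = per_subject["r_squared"].to_numpy(float)
    tt = stats.ttest_1samp(r2s, 0.0)
    return LoocvResult(
        per_subject=per_subject,
        mean_r2=float(r2s.mean()), sd_r2=float(r2s.std(ddof=1)),
        t_stat=float(tt.statistic), df=int(r2s.size - 1), p=float(tt.pvalue),
        excluded=excluded,
    )
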