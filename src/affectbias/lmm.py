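"""Mixed-effects inference linking affective bias to depression severity.

The core model regresses same-day HDRS-17 on the cell-level bias score
with fixed effects of bias, valence, their interaction, weeks since
surgical implantation and intensity class (subtle/overt), plus a random
intercept per subject; optionally also the subject's initial HDRS-17 just
after implantation, and a random intercept per cohort that is dropped when
its variance estimate is singular.  Fits use restricted maximum likelihood
(statsmodels MixedLM) and inference uses Type II Wald chi-square tests
(:mod:`affectbias._typeii`).  Valence and intensity enter under
sum-to-zero contrasts so the Type II hypothesis matrices are well defined
in the presence of the bias x valence interaction.

Model selection mirrors the two-iteration procedure of the study design:
iteration 1 includes the initial HDRS-17 covariate on the subjects that
have it; when its Wald p exceeds 0.05 iteration 2 drops the covariate and
refits on all subjects.  Separate helpers refit the final model within
each cohort and run the stimulation-status control model that gates
whether stimulation enters the main model at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._typeii import type2_wald_table

logger = logging.getLogger(__name__)

__all__ = [
    "BiasMixedModel",
    "SelectionResult",
    "StimGateResult",
    "wald_type2",
    "run_model_selection",
    "per_cohort_refits",
    "stim_control_model",
]

#: A random intercept contributing less than this fraction of the total
#: variance is treated as a singular (boundary) fit and removed.  Profiled
#: implementations (lme4) reach the boundary exactly; statsmodels stops at a
#: numerically-near-zero value, so the threshold is relative to total variance.
SINGULAR_TOL = 0.01


def wald_type2(result) -> pd.DataFrame:
    """Type II Wald chi-square ANOVA table for a formula-fitted model.

    Works for MixedLM (fixed effects only) and OLS results.  The fitted
    model must carry patsy design info (i.e. be formula-built).
    """
    di = result.model.data.design_info
    if hasattr(result, "fe_params"):
        k = len(result.fe_params)
        params = np.asarray(result.fe_params)
        cov = np.asarray(result.cov_params())[:k, :k]
    else:
        params = np.asarray(result.params)
        cov = np.asarray(result.cov_params())
    return type2_wald_table(params, cov, di)


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str,
                 vc_formula=None, re_formula="1"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM.from_formula(
            formula, data, groups=data[groups], re_formula=re_formula,
            vc_formula=vc_formula,
        )
        # variance components on the boundary trip up individual optimizers;
        # walk through a few before declaring failure
        result = None
        for method in (None, "powell", "cg"):
            kw = {} if method is None else {"method": method}
            try:
                candidate = model.fit(reml=True, **kw)
            except Exception:
                continue
            if candidate.converged:
                result = candidate
                break
    if result is None:
        raise RuntimeError(
            f"mixed-model fit did not converge for formula {formula!r} "
            f"(groups={groups}) under any optimizer"
        )
    return result


class BiasMixedModel(BaseEstimator, RegressorMixin):
    """REML mixed model of HDRS-17 (or bias) cells, sklearn-style.

    Parameters
    ----------
    response : str, default "hdrs17"
        Response column.
    bias_col : str, default "mean_bias"
        Cell-level bias column used in the bias, valence, bias x valence
        and intensity fixed-effect structure.
    include_initial : bool, default False
        Add the subject's initial post-implant HDRS-17 as a fixed effect
        (iteration-1 form).
    include_stim : bool, default False
        Add the within-cell stimulation-on fraction as a fixed effect
        (used only when the stimulation gate retains stimulation).
    cohort_re : bool, default True
        Attempt a random intercept by cohort on top of the subject
        intercept; it is removed (and recorded) when its variance estimate
        is singular or the data contain a single cohort.
    random_intercept : bool, default True
        Subject random intercept.  With False the model degenerates to an
        ordinary least-squares fit (used for single-subject cohorts).
    singular_tol : float
        Fraction of total variance below which a random-intercept variance
        is declared singular (boundary) and the term removed.

    Attributes (set by fit)
    -----------------------
    result_ : statsmodels results object
    fe_params_, cov_fe_ : fixed-effect estimates and covariance
    anova_ : Type II Wald chi-square table (term, chisq, df, p)
    var_components_ : dict of variance components incl. 'residual'
    singular_dropped_ : list of random factors removed as singular
    converged_ : bool, n_obs_ : int, formula_ : str
    """

    def __init__(self, response: str = "hdrs17", bias_col: str = "mean_bias",
                 include_initial: bool = False, include_stim: bool = False,
                 cohort_re: bool = True, random_intercept: bool = True,
                 singular_tol: float = SINGULAR_TOL):
        self.response = response
        self.bias_col = bias_col
        self.include_initial = include_initial
        self.include_stim = include_stim
        self.cohort_re = cohort_re
        self.random_intercept = random_intercept
        self.singular_tol = singular_tol

    # ------------------------------------------------------------------
    def _formula(self) -> str:
        rhs = [f"{self.bias_col} * C(valence, Sum)", "week", "C(intensity_class, Sum)"]
        if self.include_initial:
            rhs.append("initial_hdrs17")
        if self.include_stim:
            rhs.append("stim_frac")
        return f"{self.response} ~ " + " + ".join(rhs)

    def fit(self, X: pd.DataFrame, y=None):
        data = X.copy()
        self.formula_ = self._formula()
        used = [self.response, self.bias_col, "valence", "week", "intensity_class",
                "subject_id"]
        if self.include_initial:
            used.append("initial_hdrs17")
        if self.include_stim:
            used.append("stim_frac")
        missing = [c for c in used if c not in data.columns]
        if missing:
            raise ValueError(f"cells table missing columns: {missing}")
        na = data[used].isna().any(axis=1)
        if na.any():
            raise ValueError(
                f"{int(na.sum())} row(s) have missing values in model columns; "
                "filter (e.g. drop subjects without initial HDRS-17) before fitting"
            )

        self.singular_dropped_: list[str] = []
        n_subj = data["subject_id"].nunique()

        if self.random_intercept and n_subj < 2:
            raise ValueError("subject random intercept requires >= 2 subjects")

        if not self.random_intercept:
            result = smf.ols(self.formula_, data).fit()
            self._finalize(result, mixed=False)
            return self

        use_cohort = self.cohort_re and "cohort" in data.columns \
            and data["cohort"].nunique() >= 2
        if self.cohort_re and not use_cohort:
            logger.info("cohort random intercept skipped (single cohort)")

        if use_cohort:
            # A cohort intercept over two cohorts is frequently unidentifiable;
            # treat a non-converging attempt like a singular fit and drop it.
            try:
                result = _fit_mixedlm(
                    self.formula_, data, groups="cohort",
                    vc_formula={"subject": "0 + C(subject_id)"},
                )
                cohort_var = float(np.asarray(result.cov_re)[0, 0])
                total_var = cohort_var + float(result.scale) \
                    + float(np.atleast_1d(result.vcomp).sum())
                singular = cohort_var < self.singular_tol * total_var
            except RuntimeError:
                singular = True
            if singular:
                self.singular_dropped_.append("cohort")
                logger.info("cohort random intercept singular or unstable; removed")
                result = _fit_mixedlm(self.formula_, data, groups="subject_id")
                self._finalize(result, mixed=True, re_name="subject")
            else:
                self._finalize(result, mixed=True, re_name="cohort")
        else:
            result = _fit_mixedlm(self.formula_, data, groups="subject_id")
            self._finalize(result, mixed=True, re_name="subject")
        return self

    def _finalize(self, result, mixed: bool, re_name: str = "subject"):
        self.result_ = result
        if mixed:
            k = len(result.fe_params)
            self.fe_params_ = result.fe_params.copy()
            self.cov_fe_ = pd.DataFrame(
                np.asarray(result.cov_params())[:k, :k],
                index=self.fe_params_.index, columns=self.fe_params_.index,
            )
            vcs = {"residual": float(result.scale)}
            if result.k_re:
                vcs[re_name] = float(np.asarray(result.cov_re)[0, 0])
            if result.model.exog_vc is not None and result.model.k_vc:
                for vc_name, val in zip(result.model.exog_vc.names,
                                        np.atleast_1d(result.vcomp)):
                    vcs[vc_name] = float(val)
            self.var_components_ = vcs
        else:
            self.fe_params_ = result.params.copy()
            self.cov_fe_ = pd.DataFrame(
                np.asarray(result.cov_params()),
                index=self.fe_params_.index, columns=self.fe_params_.index,
            )
            self.var_components_ = {"residual": float(result.mse_resid)}
        self.converged_ = bool(getattr(result, "converged", True))
        self.n_obs_ = int(result.model.exog.shape[0])
        self.anova_ = wald_type2(result)
        return self

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction from fixed effects only.

        Random intercepts are set to zero, which is the only defensible
        prediction for a subject absent from the training data.
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("BiasMixedModel is not fitted")
        return np.asarray(self.result_.predict(exog=X), float)

    def term_p(self, term: str) -> float:
        row = self.anova_.loc[self.anova_["term"] == term]
        if len(row) != 1:
            raise KeyError(f"term {term!r} not in ANOVA table "
                           f"({list(self.anova_['term'])})")
        return float(row["p"].iloc[0])

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula_,
            "n_obs": self.n_obs_,
            "converged": self.converged_,
            "coefficients": {k: float(v) for k, v in self.fe_params_.items()},
            "cov_fixed": self.cov_fe_.to_numpy().tolist(),
            "var_components": self.var_components_,
            "singular_dropped": self.singular_dropped_,
            "anova": self.anova_.to_dict(orient="records"),
        }


# ----------------------------------------------------------------------
@dataclass
class SelectionResult:
    iteration1: BiasMixedModel | None
    iteration2: BiasMixedModel | None
    final: BiasMixedModel
    trail: list[str] = field(default_factory=list)

    @property
    def anova(self) -> pd.DataFrame:
        return self.final.anova_


def run_model_selection(cells: pd.DataFrame, alpha: float = 0.05,
                        include_stim: bool = False) -> SelectionResult:
    """Two-iteration HDRS~Bias model selection with decision trail.

    Iteration 1 adds the initial post-implant HDRS-17 covariate, fitted on
    the subjects that have it; when its Type II Wald p exceeds ``alpha``
    the covariate is dropped and iteration 2 refits on all subjects.  Both
    iterations first attempt a cohort random intercept and remove it on a
    singular fit.
    """
    trail: list[str] = []
    if "initial_hdrs17" not in cells.columns:
        raise ValueError("cells table lacks 'initial_hdrs17'; iteration 1 impossible")
    have_init = cells["initial_hdrs17"].notna()
    dropped_subj = sorted(set(cells.loc[~have_init, "subject_id"]))
    if dropped_subj:
        trail.append(
            f"iteration 1 excludes {len(dropped_subj)} subject(s) missing "
            f"initial HDRS-17: {dropped_subj}"
        )
    it1 = BiasMixedModel(include_initial=True, include_stim=include_stim)
    it1.fit(cells.loc[have_init])
    if it1.singular_dropped_:
        trail.append(f"iteration 1: singular random intercept(s) removed: "
                     f"{it1.singular_dropped_}")
    p_init = it1.term_p("initial_hdrs17")
    trail.append(f"initial HDRS-17 Wald p = {p_init:.4g}")

    if p_init > alpha:
        it2 = BiasMixedModel(include_initial=False, include_stim=include_stim)
        it2.fit(cells)
        if it2.singular_dropped_:
            trail.append(f"iteration 2: singular random intercept(s) removed: "
                         f"{it2.singular_dropped_}")
        trail.append(
            f"initial HDRS-17 non-significant (p > {alpha}); iteration 2 "
            f"refit on all {cells['subject_id'].nunique()} subjects"
        )
        final = it2
    else:
        it2 = None
        trail.append(f"initial HDRS-17 significant (p <= {alpha}); iteration 1 retained")
        final = it1
    return SelectionResult(iteration1=it1, iteration2=it2, final=final, trail=trail)


def per_cohort_refits(cells: pd.DataFrame, cohorts=("E", "B")) -> dict[str, BiasMixedModel]:
    """Refit the iteration-2 model within each cohort separately."""
    out: dict[str, BiasMixedModel] = {}
    for cohort in cohorts:
        sub = cells.loc[cells["cohort"] == cohort]
        if len(sub) == 0:
            raise ValueError(f"cohort {cohort!r} has no cells")
        n_subj = sub["subject_id"].nunique()
        if n_subj < 2:
            warnings.warn(
                f"cohort {cohort!r} has {n_subj} subject(s); subject random "
                "intercept dropped", stacklevel=2,
            )
            model = BiasMixedModel(include_initial=False, cohort_re=False,
                                   random_intercept=False)
        else:
            if n_subj == 2:
                warnings.warn(
                    f"cohort {cohort!r} has only 2 subjects; subject random "
                    "intercept kept but its variance is weakly identified",
                    stacklevel=2,
                )
            model = BiasMixedModel(include_initial=False, cohort_re=False)
        out[cohort] = model.fit(sub)
    return out


# ----------------------------------------------------------------------
@dataclass
class StimGateResult:
    model: BiasMixedModel
    stim_p: float
    exclude_stimulation: bool
    n_blocks_on: int
    n_blocks_off: int

    def as_dict(self) -> dict:
        return {
            "stim_p": self.stim_p,
            "exclude_stimulation": self.exclude_stimulation,
            "n_blocks_on": self.n_blocks_on,
            "n_blocks_off": self.n_blocks_off,
            "anova": self.model.anova_.to_dict(orient="records"),
        }


def stim_control_model(scores: pd.DataFrame, alpha: float = 0.05) -> StimGateResult:
    """Bias ~ Stim control model on trials with on/off stimulation.

    Uses only the visits at which the task was collected under both
    stimulation states (the paired on/off administrations, giving
    balanced on/off block counts), aggregates scored non-neutral trials
    to block x intensity-class units (the finest unit with a homogeneous
    stimulation state) and fits bias ~ stimulation status + days since
    implant + valence + intensity with a subject random intercept.
    Returns the stimulation-status Wald p and the gate decision
    ``exclude_stimulation = (p > alpha)``.
    """
    s = scores.loc[scores["valence"] != "neutral"].copy()
    if len(s) == 0:
        raise ValueError("no non-neutral scored trials")
    paired = s.groupby(["subject_id", "session_date"])["stim_on"].transform("nunique") == 2
    s = s.loc[paired]
    if len(s) == 0:
        raise ValueError("no session observed under both stimulation states")
    from .scoring import intensity_class

    s["intensity_class"] = intensity_class(s["intensity"]).to_numpy()
    states = s.groupby("subject_id")["stim_on"].nunique()
    if (states < 2).any():
        bad = list(states.index[states < 2])
        raise ValueError(f"subject(s) {bad} observed under a single stimulation state")

    units = (
        s.groupby(["subject_id", "session_date", "week", "block_index",
                   "stim_on", "valence", "intensity_class"], sort=True)
        .agg(mean_bias=("bias", "mean"))
        .reset_index()
    )
    units["days"] = units["week"] * 7.0
    units["stim"] = units["stim_on"].map({True: "on", False: "off"})

    formula = "mean_bias ~ C(stim) + days + C(valence, Sum) + C(intensity_class, Sum)"
    result = _fit_mixedlm(formula, units, groups="subject_id")
    model = BiasMixedModel(response="mean_bias")  # container for reporting
    model.formula_ = formula
    model.singular_dropped_ = []
    model._finalize(result, mixed=True, re_name="subject")
    stim_p = model.term_p("stim")
    return StimGateResult(
        model=model, stim_p=stim_p, exclude_stimulation=bool(stim_p > alpha),
        n_blocks_on=int(units.loc[units["stim_on"]].groupby(
            ["subject_id", "session_date", "block_index"]).ngroups),
        n_blocks_off=int(units.loc[~units["stim_on"]].groupby(
            ["subject_id", "session_date", "block_index"]).ngroups),
    )
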