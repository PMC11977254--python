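"""Synthetic control and patient cohorts with the design of the DBS trials.

The generator emulates the statistical structure the analysis chain
assumes, so every stage is testable without any clinical download:

* **Controls** rate each face around a smooth odd psychometric curve
  mu(s) = 0.5 + 0.5 * k * sign(s) * |s/100|^c of the signed morph
  intensity s, with additive Gaussian noise (clamped to [0, 1]) and a
  small fraction of uniform-random outlier ratings for the trimming rule
  to catch.  A screening pool of 400 raters with integer symptom scores
  yields the configured number of symptom-free controls.
* **Patients** (two site styles: 'E' monthly visits with paired on/off
  stimulation administrations, 'B' biweekly visits with long study
  pauses) rate the same faces with an added latent affective bias
  B_i(t) = (B0 + b_i) * decay(t) + eta_it that starts negative and
  attenuates over treatment (exponential decay by default, linear
  optionally).  The valence-asymmetry parameter allocates the bias across
  valences; at its default of 1 the entire bias is carried by happy
  faces, so the sad-trial pre/post contrast is null by construction.
* **HDRS-17** trajectories are generated as
  alpha + u_i + gamma * B_i(t) + beta_week * t + noise, rounded and
  clipped to the instrument's 0-52 range, with gamma < 0 so that a more
  negative bias accompanies more severe depression.

Every dataset is deterministic under a fixed seed and ships with its
generating truth (per-subject intercepts, per-visit latent bias, all
coefficients) for parameter-recovery studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stimuli

__all__ = [
    "GeneratorConfig",
    "DirectCellConfig",
    "SCENARIOS",
    "scenario_config",
    "gen_controls",
    "gen_control_pool",
    "gen_patients",
    "generate_dataset",
    "gen_cells_direct",
]

MONTHLY_WEEKS = (1.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)


def _biweekly_schedule(index: int) -> tuple[float, ...]:
    """Biweekly visits over ~5 months of programming plus a pre-surgical
    baseline; alternate subjects carry the two long study pauses
    (177 and 244 days) seen in practice."""
    base = [-1.0] + [1.0 + 2.0 * i for i in range(11)]  # weeks -1, 1, 3, ..., 21
    if index % 2 == 0:
        gap_after, gap_weeks = 9.0, 177.0 / 7.0
    else:
        gap_after, gap_weeks = 11.0, 244.0 / 7.0
    return tuple(w if w <= gap_after else w + gap_weeks for w in base)


@dataclass
class GeneratorConfig:
    """Study-shaped generating conditions (defaults are the study design)."""

    # controls / norms
    n_controls: int = 86
    n_control_pool: int = 400
    control_noise_sd: float = 0.08
    control_outlier_rate: float = 0.02
    psychometric_gain: float = 0.9     # k: rating swing at the 100% morphs
    psychometric_curvature: float = 0.7  # c: concavity of the morph response
    # cohorts and schedules
    n_monthly: int = 8
    n_biweekly: int = 2
    monthly_weeks: tuple = MONTHLY_WEEKS
    # affective bias course
    initial_bias: float = -0.06        # B0, on the rating scale
    subject_bias_sd: float = 0.02      # SD of b_i
    bias_tau_weeks: float = 10.0       # exponential decay constant
    bias_course: str = "exp"           # 'exp' or 'linear'
    visit_bias_sd: float = 0.02        # eta_it, per-visit latent wobble
    valence_asymmetry: float = 1.0     # fraction of bias carried by happy trials
    # rating noise
    patient_noise_sd: float = 0.08
    subject_offset_sd: float = 0.01    # idiosyncratic rating-scale offset
    # HDRS model
    hdrs_alpha: float = 22.0
    hdrs_subject_sd: float = 2.0
    hdrs_gamma: float = -40.0          # HDRS units per unit latent bias (< 0)
    hdrs_week_slope: float = -0.15     # HDRS units per week
    hdrs_noise_sd: float = 1.2
    # the post-implant snapshot: a single noisy measurement whose range is
    # restricted by the trial's severity inclusion criterion, hence carrying
    # no information about the trajectory beyond its mean
    initial_hdrs_sd: float = 2.0
    # stimulation
    stim_effect: float = 0.0           # acute rating shift while stim is on
    # bookkeeping
    n_missing_initial: int = 1         # E subjects lacking the initial HDRS-17

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["monthly_weeks"] = list(self.monthly_weeks)
        return d

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


SCENARIOS: dict[str, dict] = {
    # the study conditions themselves
    "study_shape": {},
    # no bias, no coupling: every downstream p-value should be null-calibrated
    "null": {"initial_bias": 0.0, "subject_bias_sd": 0.0, "visit_bias_sd": 0.0,
             "hdrs_gamma": 0.0, "hdrs_week_slope": 0.0},
    # an exaggerated treatment effect for power demonstrations
    "strong_effect": {"initial_bias": -0.10, "hdrs_gamma": -60.0,
                      "hdrs_noise_sd": 1.0, "patient_noise_sd": 0.06},
    # an acute stimulation effect the control model must detect
    "stim_effect": {"stim_effect": 0.1},
}


def scenario_config(name: str, **overrides) -> GeneratorConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return GeneratorConfig(**{**SCENARIOS[name], **overrides})


# ----------------------------------------------------------------------
def _psychometric_mean(signed_intensity, cfg: GeneratorConfig):
    x = np.asarray(signed_intensity, float) / 100.0
    g = cfg.psychometric_gain * np.sign(x) * np.abs(x) ** cfg.psychometric_curvature
    return np.clip(0.5 + 0.5 * g, 0.0, 1.0)


def _decay(weeks, cfg: GeneratorConfig):
    t = np.maximum(np.asarray(weeks, float), 0.0)
    if cfg.bias_course == "exp":
        return np.exp(-t / cfg.bias_tau_weeks)
    if cfg.bias_course == "linear":
        return np.maximum(1.0 - t / (2.0 * cfg.bias_tau_weeks), 0.0)
    raise ValueError(f"bias_course must be 'exp' or 'linear', got {cfg.bias_course!r}")


def _valence_weight(valence, cfg: GeneratorConfig):
    """Allocate the latent (total) bias across valences; neutral gets none.

    Weights are 2a for happy and 2(1-a) for sad so the mean over the two
    emotional valences equals the latent total bias."""
    a = cfg.valence_asymmetry
    v = pd.Series(valence)
    return v.map({"happy": 2.0 * a, "sad": 2.0 * (1.0 - a), "neutral": 0.0}).to_numpy()


def gen_control_pool(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Screening pool: integer symptom scores, exactly ``n_controls`` zeros."""
    n = cfg.n_control_pool
    scores = np.zeros(n, int)
    scores[cfg.n_controls:] = rng.integers(1, 15, size=n - cfg.n_controls)
    rng.shuffle(scores)
    return pd.DataFrame({
        "rater_id": [f"C{i + 1:03d}" for i in range(n)],
        "screen_score": scores,
    })


def gen_controls(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    registry: list | None = None,
    rater_ids=None,
) -> pd.DataFrame:
    """Control rating table: every retained rater rates every face once."""
    registry = registry if registry is not None else stimuli.build_registry()
    reg = stimuli.registry_frame(registry)
    if rater_ids is None:
        rater_ids = [f"C{i + 1:03d}" for i in range(cfg.n_controls)]
    n_r, n_f = len(rater_ids), len(reg)
    mu = _psychometric_mean(reg["signed_intensity"].to_numpy(), cfg)
    ratings = np.clip(
        np.tile(mu, n_r) + rng.normal(0.0, cfg.control_noise_sd, n_r * n_f), 0.0, 1.0
    )
    outlier = rng.random(n_r * n_f) < cfg.control_outlier_rate
    ratings[outlier] = rng.random(int(outlier.sum()))
    out = pd.concat([reg] * n_r, ignore_index=True)
    out.insert(0, "rater_id", np.repeat(rater_ids, n_f))
    out["rating"] = ratings
    return out


# ----------------------------------------------------------------------
def _subject_plan(cfg: GeneratorConfig):
    plan = []
    for i in range(cfg.n_monthly):
        plan.append((f"E{i + 1:03d}", "E", tuple(cfg.monthly_weeks), i))
    for j in range(cfg.n_biweekly):
        plan.append((f"B{j + 1:03d}", "B", _biweekly_schedule(j), j))
    return plan


def gen_patients(cfg: GeneratorConfig, rng: np.random.Generator,
                 registry: list | None = None):
    """Patient trials, clinical records and the generating truth.

    Returns ``(trials, clinical, truth)``.  monthly-visit ('E') style first outpatient
    visits are collected entirely without stimulation (stimulation is not
    yet on); later 'E'-style visits pair an on administration with an off
    administration.  biweekly-visit ('B') style visits are all-on except the
    pre-surgical baseline.
    """
    registry = registry if registry is not None else stimuli.build_registry()
    plan = _subject_plan(cfg)

    trial_frames = []
    clin_rows = []
    truth = {"config": cfg.as_dict(), "subjects": {}}
    for s_idx, (subj, style, weeks, within_idx) in enumerate(plan):
        b_i = rng.normal(0.0, cfg.subject_bias_sd)
        u_i = rng.normal(0.0, cfg.hdrs_subject_sd)
        r_i = rng.normal(0.0, cfg.subject_offset_sd)
        implant = pd.Timestamp("2020-01-06") + pd.Timedelta(days=35 * s_idx)
        initial_hdrs = int(np.clip(round(
            cfg.hdrs_alpha + rng.normal(0.0, cfg.initial_hdrs_sd)), 0, 52))
        if cfg.n_missing_initial == 1 and cfg.n_monthly >= 5:
            missing_initial = style == "E" and within_idx == 4  # the fifth subject
        else:
            missing_initial = (style == "E"
                               and within_idx >= cfg.n_monthly - cfg.n_missing_initial)
        subj_truth = {"b_i": b_i, "u_i": u_i, "r_i": r_i,
                      "initial_hdrs17": None if missing_initial else initial_hdrs,
                      "visits": {}}

        for v_idx, week in enumerate(weeks):
            date = implant + pd.Timedelta(days=int(round(week * 7)))
            stim_plan = "all_off" if (style == "E" and v_idx == 0) else "standard"
            session = stimuli.build_session(
                subj, style, week, rng, registry=registry, stim_plan=stim_plan,
                counterbalance=within_idx, session_date=date,
            )
            frame = stimuli.session_frame(session)
            latent = (cfg.initial_bias + b_i) * float(_decay(week, cfg)) \
                + rng.normal(0.0, cfg.visit_bias_sd)
            mu = _psychometric_mean(frame["signed_intensity"].to_numpy(), cfg)
            w = _valence_weight(frame["valence"], cfg)
            stim = frame["stim_on"].to_numpy()
            noise = rng.normal(0.0, cfg.patient_noise_sd, len(frame))
            frame["rating"] = np.clip(
                mu + w * latent + cfg.stim_effect * stim + r_i + noise, 0.0, 1.0
            )
            trial_frames.append(frame)

            hdrs = int(np.clip(round(
                cfg.hdrs_alpha + u_i + cfg.hdrs_gamma * latent
                + cfg.hdrs_week_slope * max(week, 0.0)
                + rng.normal(0.0, cfg.hdrs_noise_sd)), 0, 52))
            clin_rows.append({
                "subject_id": subj, "date": date, "week": week, "hdrs17": hdrs,
                "implant_date": implant,
                "initial_hdrs17": np.nan if missing_initial else initial_hdrs,
            })
            subj_truth["visits"][f"{week:g}"] = {"latent_bias": latent, "hdrs17": hdrs}
        truth["subjects"][subj] = subj_truth

    trials = pd.concat(trial_frames, ignore_index=True)
    clinical = pd.DataFrame(clin_rows)
    return trials, clinical, truth


def generate_dataset(cfg: GeneratorConfig | None = None, seed: int = 0) -> dict:
    """Controls + screening pool + patient trials + clinical records + truth.

    All randomness descends from ``seed`` through independent substreams
    (controls and patients are separately reproducible); the same seed
    yields a byte-identical dataset.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    root = np.random.default_rng(seed)
    rng_screen, rng_controls, rng_patients = root.spawn(3)
    registry = stimuli.build_registry()
    pool = gen_control_pool(cfg, rng_screen)
    retained = pool.loc[pool["screen_score"] <= 0, "rater_id"].tolist()
    controls = gen_controls(cfg, rng_controls, registry=registry, rater_ids=retained)
    trials, clinical, truth = gen_patients(cfg, rng_patients, registry=registry)
    truth["seed"] = seed
    return {"controls": controls, "screen": pool, "trials": trials,
            "clinical": clinical, "truth": truth}


# ----------------------------------------------------------------------
@dataclass
class DirectCellConfig:
    """Cell-level data generated directly under the fitted model's form.

    Used for parameter recovery: the response is literally
    intercept + u_i + gamma * bias + week_slope * week + noise, so the
    fitted coefficients estimate gamma and week_slope without any
    mechanistic indirection."""

    gamma: float = -5.0        # HDRS units per bias unit
    week_slope: float = -0.15  # HDRS units per week
    intercept: float = 22.0
    subject_sd: float = 2.0
    resid_sd: float = 1.0
    bias_center: float = -0.04
    bias_sd: float = 0.03
    bias_tau_weeks: float = 10.0
    initial_coef: float = 0.0  # dependence of HDRS on the initial score
    n_monthly: int = 8
    n_biweekly: int = 2
    monthly_weeks: tuple = MONTHLY_WEEKS


def gen_cells_direct(cfg: DirectCellConfig, rng: np.random.Generator):
    """Generate an analysis-cell table straight from the LME's own form.

    Returns ``(cells, truth)`` where truth holds the generating
    coefficients.  Each visit contributes the four valence x intensity
    cells; the cell bias decays over weeks around ``bias_center`` so bias
    and week are correlated (as in the study) but retain independent
    variation."""
    rows = []
    plan = [(f"E{i + 1:03d}", "E", tuple(cfg.monthly_weeks), i) for i in range(cfg.n_monthly)]
    plan += [(f"B{j + 1:03d}", "B", _biweekly_schedule(j), j) for j in range(cfg.n_biweekly)]
    for subj, cohort, weeks, _ in plan:
        u_i = rng.normal(0.0, cfg.subject_sd)
        # an independent snapshot: informative about HDRS only via initial_coef
        init_i = float(np.clip(round(cfg.intercept + rng.normal(0.0, 2.0)), 0, 52))
        for week in weeks:
            if week < 0:
                continue
            for valence in ("happy", "sad"):
                for iclass in ("subtle", "overt"):
                    bias = cfg.bias_center * np.exp(-week / cfg.bias_tau_weeks) \
                        + rng.normal(0.0, cfg.bias_sd)
                    hdrs = (cfg.intercept + u_i + cfg.gamma * bias
                            + cfg.week_slope * week
                            + cfg.initial_coef * (init_i - cfg.intercept)
                            + rng.normal(0.0, cfg.resid_sd))
                    rows.append({
                        "subject_id": subj, "cohort": cohort,
                        "session_date": f"wk{week:g}", "week": week,
                        "valence": valence, "intensity_class": iclass,
                        "mean_bias": bias, "n_trials": 24,
                        "hdrs17": hdrs, "initial_hdrs17": init_i,
                        "stim_frac": 0.5,
                    })
    cells = pd.DataFrame(rows)
    truth = {"gamma": cfg.gamma, "week_slope": cfg.week_slope,
             "intercept": cfg.intercept, "initial_coef": cfg.initial_coef}
    return cells, truth
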