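# Methods

## The measurement model

The affective bias task presents morphed face photographs whose expression
spans a sad–happy continuum.  Stimuli are treated purely as metadata: an
exemplar is an (identity, signed intensity) pair, with signed intensity
s ∈ {−100, −50, −30, −10, 0, +10, +30, +50, +100} (negative = sad,
0 = neutral, positive = happy) as the canonical coordinate.  The default
registry of 6 identities × 9 levels = 54 exemplars, 30-trial single-valence
blocks (all happy or all sad faces plus all neutrals, each exactly once in
seeded random order), and the two site-specific visit structures (two
administrations with a paired stimulation-on/off contrast and the negative
block first, vs. three all-on administrations with counterbalanced block
order) reproduce the design of the two-site DBS trial the package targets.

**Norms.** For each face, control ratings (scale 0 = very sad, 0.5 =
neutral, 1 = very happy) are summarized by a single-pass trimmed mean: the
mean m and sample SD s (n−1 denominator) are computed once over all
ratings, ratings with |r − m| > 2s are excluded (strict inequality — a
rating exactly at 2s is retained, reading "more than two SDs" literally),
and the expected score is the mean of what remains.  A one-pass rule
cannot empty a face's rating set (at most a quarter of points can lie
beyond 2 SDs); a zero or numerically underflowed SD disables trimming for
that face.  Trimming is deliberately not iterated: re-trimming would be a
different estimator and the single pass is the literal protocol.

**Bias.** A patient trial's bias is observed rating − expected score, on
the rating scale (possible range [−1, 1]); no rescaling is applied
anywhere, and all downstream coefficients are in these units.

## Units of analysis

The mixed models operate on **cells** — one row per subject × visit ×
valence × intensity class over the non-neutral trials, where subtle =
{10, 30}% and overt = {50, 100}% morphs (the only balanced 2+2 split of
the four levels).  Same-day HDRS-17 is constant within a visit, so
trial-level modeling would pseudo-replicate each clinical score hundreds
of times; the cell is the finest unit that still provides within-visit
valence and intensity contrasts.  Sessions lacking a same-day HDRS-17 are
dropped with a logged count.  The pre/post contrast, by design, works at
trial level (it involves no clinical score): pre is the first outpatient
visit preceding stimulation onset (falling back to the latest pre-onset
session, in practice a pre-surgical baseline, for subjects missing that
visit), post is the final visit, and stimulation-on and -off trials of a
visit are pooled.

## Inference

**Pre/post.**  Equal-variance two-sample t; the permutation test shuffles
the pooled trials into pseudo-groups of the original sizes and recomputes
the pooled t, with p = #(pseudo t ≤ true t)/N — one-sided exactly as the
protocol prints it (improvement makes the true t negative), ties counted
in the numerator, a two-sided doubling available behind a flag but off by
default.  Zero-variance pseudo-samples contribute t = 0 (logged); a zero
count is displayed as "< 1/N" and stored as 0.0.

**Mixed models.**  REML throughout (statsmodels MixedLM).  Valence and
intensity enter under sum-to-zero contrasts so the Type II hypothesis
matrices are well defined in the presence of the bias × valence
interaction; Type II Wald χ² values are invariant to that coding choice
under correct marginality handling.  The Type II construction follows the
marginality principle as implemented in R's `car` package: for a term with
higher-order relatives, the hypothesis matrix spans the complement of the relatives'
rows within the relatives+term row space under the coefficient-covariance
inner product; χ² = (Lβ)ᵀ(LΣLᵀ)⁻¹(Lβ), df = rank(L).  For terms without
relatives this reduces exactly to the marginal Wald test, and for
single-coefficient terms to (estimate/SE)².  An R cross-check against
car::Anova on identical data agrees exactly for OLS and to optimizer
precision for REML mixed fits.

**Singular fits.**  A cohort random intercept is attempted on top of the
subject intercept (cohorts as groups, subjects as nested variance
components).  It is removed when its variance contributes less than 1% of
the total variance.  Profiled implementations (lme4) land exactly on the
boundary in this situation; statsmodels stops at a numerically-near-zero
value (typically 10⁻³–10⁻² of the residual variance), so a
machine-epsilon threshold would never fire — the 1% rule reproduces
lme4's `isSingular` verdicts on matched datasets while leaving genuine
cohort variance (which, when simulated, is an order of magnitude above
threshold) untouched.  A non-converging cohort attempt is treated the same
way; with two cohort levels the variance is weakly identified and roughly
40% of null-cohort replicates land on a positive variance estimate rather
than the boundary, which matches lme4's behavior on the same data.
Optimizer fallbacks (default, then Powell, then CG) guard against
boundary-induced failures of any single method.

**Model selection.**  Iteration 1 adds the initial post-implant HDRS-17
(excluding subjects missing it); if its Type II Wald p exceeds 0.05 the
covariate is dropped and iteration 2 refits on all subjects.  The gate for
including stimulation status in the main model is the separate
Bias ~ Stim + Days + Valence + Intensity + (1|Subject) model, fitted on
block × intensity-class units from the visits with paired on/off
administrations only — restricting to paired visits keeps the on/off
block counts balanced and removes the confound between stimulation state
and treatment phase that the all-off first visit would otherwise
introduce.  Because the paired administrations share a visit-level mood
state that the subject-only intercept does not model, the stimulation SE
is, if anything, overestimated and the gate errs toward exclusion; its
empirical false-retention rate is below the nominal 5%.

**LOOCV.**  Each held-out subject's HDRS-17 is predicted from fixed
effects only — the only defensible choice for an unseen subject, and one
that bounds attainable R² — with cell predictions averaged per visit.
R² is the squared Pearson correlation (guaranteed [0, 1]); the
coefficient-of-determination variant (1 − SSE/SST, unbounded below) is
available behind a flag.  Subjects need ≥ 3 visits to be tested; constant
observed trajectories are excluded (correlation undefined).  The
one-sample t-test of the R² values against zero is anti-conservative by
construction (the values are nonnegative); it is reported as designed
rather than corrected.

## The synthetic generator

`synth.GeneratorConfig` defaults encode the study conditions: 86 controls
retained from a 400-rater screening pool (symptom score ≤ 0), rating each
face around an odd monotone psychometric curve
μ(s) = 0.5 + 0.5·k·sign(s)|s/100|^c (k = 0.9, c = 0.7) with SD-0.08 noise
and a 2% uniform-outlier rate; 8 monthly-visit subjects (weeks 1–24, first
outpatient visit entirely stimulation-off, later visits with paired on/off
administrations) and 2 biweekly-visit subjects carrying the 177-day and
244-day study pauses as schedule gaps only; a latent affective bias
B_i(t) = (B₀ + b_i)·e^(−t/τ) + η_it with B₀ = −0.06, τ = 10 weeks (a
linear course is available), allocated across valences by the asymmetry
parameter — at its default of 1 the happy-face trials carry the entire
bias (weight 2 so the two-valence mean equals B) and the sad-trial
pre/post contrast is null by construction; and HDRS-17 trajectories
α + u_i + γ·B_i(t) + β_w·t + ε rounded and clipped to 0–52, with α = 22
(the cohorts' baseline severity), γ = −40 HDRS per bias unit, β_w = −0.15
per week and SD-1.2 residuals.  The initial post-implant HDRS-17 is
generated as an independent noisy snapshot around α: the trial's severity
inclusion criterion restricts its range, and in the study it carried no
information about the trajectories (the covariate was dropped at model
selection), which is the condition the generator encodes.  One monthly-visit
subject (the fifth) lacks the initial score, exercising the iteration-1
exclusion path.  Effect sizes are design-matched, not data-matched — the
clinical data are not public — so reproduced quantities are qualitative
patterns and operating characteristics, not the trial's printed statistics.

For parameter-recovery studies a second generator
(`synth.gen_cells_direct`) emits cell tables straight from the fitted
model's own equation (γ = −5 HDRS/bias-unit, week slope −0.15 by default),
so "truth" lives on the same scale as the estimates.

What the generator does **not** emulate: rater demographics and age
effects, reaction times, per-identity idiosyncrasies in patients,
medication changes, within-visit order/fatigue effects, and any
instrument-specific HDRS item structure.  Passing tests therefore show
that the chain recovers what it assumes, under realistic sample sizes and
noise — not that real trial data satisfy those assumptions.

## Problem sizes in the test suite

Calibration and recovery suites use 500 null datasets × 1,000 permutation
iterations, 200 recovery cohorts of 10 subjects, 120 + 40 gate replicates
and 100 end-to-end pattern replicates — sizes at which binomial error on
the asserted rates is a few percent and the whole suite completes in a few
minutes on one core.  Permutation exactness is checked against full
enumeration at n = 4 + 4 (70 splits).

## Known limitations

* The per-term χ² values of the source trial's tables are functions of the
  unreleased clinical data and are not reproduction targets.
* Degrees of freedom are Wald-χ² only; no Satterthwaite/Kenward–Roger
  small-sample corrections.
* The two-subject cohort's random-intercept variance is weakly identified;
  the per-cohort refit keeps the intercept and warns.
* Cell- vs. trial-level modeling is a package decision (cells avoid
  pseudo-replication of same-day clinical scores); trial-level bias enters
  only the pre/post contrasts and the stimulation gate.
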