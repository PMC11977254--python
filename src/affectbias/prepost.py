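"""Pre/post-treatment contrasts: pooled-variance t-tests and permutation inference.

The pre/post comparison pools trial-level bias scores from every subject's
selected pre-DBS and post-DBS sessions and runs an equal-variance
(Student) two-sample t-test.  Robustness is assessed by a label-shuffling
permutation test: the pooled scores are randomly relabelled into
pseudo-pre and pseudo-post groups of the original sizes, the pooled t is
recomputed each iteration, and the permutation p-value is

    p_perm = #(pseudo t <= true t) / n_iterations

— one-sided in the direction where improvement makes the true t negative,
ties counting toward the numerator.  A two-sided variant (doubling the
smaller tail) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TTestResult", "PermutationResult", "student_t", "permutation_test",
           "prepost_contrasts"]


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    n_pre: int
    n_post: int
    mean_pre: float
    mean_post: float

    def as_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p_two_sided": self.p_two_sided,
            "n_pre": self.n_pre, "n_post": self.n_post,
            "mean_pre": self.mean_pre, "mean_post": self.mean_post,
        }


@dataclass
class PermutationResult:
    true_t: float
    n_iterations: int
    n_pseudo_leq: int
    p_perm: float
    seed: int | None
    two_sided: bool = False

    def display_p(self) -> str:
        """Zero counts are reported as a bound, not as an exact zero."""
        if self.n_pseudo_leq == 0:
            return f"< {1.0 / self.n_iterations:g}"
        return f"{self.p_perm:g}"

    def as_dict(self) -> dict:
        return {
            "true_t": self.true_t, "n_iterations": self.n_iterations,
            "n_pseudo_leq": self.n_pseudo_leq, "p_perm": self.p_perm,
            "p_display": self.display_p(), "seed": self.seed,
            "two_sided": self.two_sided,
        }


def _pooled_t(pre: np.ndarray, post: np.ndarray) -> float:
    n1, n2 = pre.size, post.size
    v = ((n1 - 1) * pre.var(ddof=1) + (n2 - 1) * post.var(ddof=1)) / (n1 + n2 - 2)
    if v <= 0:
        raise ZeroDivisionError("zero pooled variance")
    return (pre.mean() - post.mean()) / np.sqrt(v * (1 / n1 + 1 / n2))


def student_t(pre, post) -> TTestResult:
    """Equal-variance two-sample t-test of pre vs post bias scores."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("need at least two observations per group")
    try:
        t = _pooled_t(pre, post)
    except ZeroDivisionError:
        raise ValueError("degenerate input: zero pooled variance") from None
    df = pre.size + post.size - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=int(df), p_two_sided=float(p),
                       n_pre=int(pre.size), n_post=int(post.size),
                       mean_pre=float(pre.mean()), mean_post=float(post.mean()))


def permutation_test(
    pre,
    post,
    n_iterations: int = 5000,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = False,
    batch: int = 500,
) -> PermutationResult:
    """Label-shuffling permutation test on the pooled t-statistic.

    Each iteration partitions the pooled scores uniformly at random into
    pseudo-pre (size n_pre) and pseudo-post (size n_post) and recomputes
    the pooled t.  With ``two_sided=False`` (the default) the p-value is
    the one-sided #(pseudo t <= true t)/N with ties counted; with
    ``two_sided=True`` the smaller of the two tails is doubled (capped at
    1).  An iteration with zero pooled variance contributes t = 0 (logged).
    Deterministic under a fixed seed.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    res = student_t(pre, post)  # validates input
    true_t = res.t
    n1 = pre.size
    pooled = np.concatenate([pre, post])
    n = pooled.size

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pseudo = np.empty(n_iterations)
    n_degenerate = 0
    denom_df = n - 2
    for start in range(0, n_iterations, batch):
        b = min(batch, n_iterations - start)
        # a random permutation per row: argsort of iid uniforms
        idx = np.argsort(rng.random((b, n)), axis=1)
        sample = pooled[idx]
        g1 = sample[:, :n1]
        g2 = sample[:, n1:]
        v = ((n1 - 1) * g1.var(axis=1, ddof=1) + (n - n1 - 1) * g2.var(axis=1, ddof=1)) / denom_df
        se = np.sqrt(v * (1 / n1 + 1 / (n - n1)))
        diff = g1.mean(axis=1) - g2.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        n_degenerate += int((se <= 0).sum())
        pseudo[start:start + b] = t
    if n_degenerate:
        logger.warning("%d permutation iteration(s) had zero pooled variance; t set to 0",
                       n_degenerate)

    n_leq = int((pseudo <= true_t).sum())
    if two_sided:
        n_geq = int((pseudo >= true_t).sum())
        p = min(1.0, 2.0 * min(n_leq, n_geq) / n_iterations)
    else:
        p = n_leq / n_iterations
    return PermutationResult(true_t=float(true_t), n_iterations=int(n_iterations),
                             n_pseudo_leq=n_leq, p_perm=float(p), seed=seed_val,
                             two_sided=two_sided)


def prepost_contrasts(
    pre_scores,
    post_scores,
    n_iterations: int = 5000,
    seed=None,
    aggregations=("total", "positive", "negative"),
) -> dict:
    """t-test + permutation test per aggregation on one pre/post partition.

    ``pre_scores``/``post_scores`` are scored trial tables (with ``bias``
    and ``valence`` columns); all three contrasts use the same partition,
    so the positive- and negative-trial counts sum to the total's.
    """
    from .scoring import aggregate_bias

    rng = np.random.default_rng(seed)
    out = {}
    for agg in aggregations:
        _, pre_kept = aggregate_bias(pre_scores, agg)
        _, post_kept = aggregate_bias(post_scores, agg)
        pre_b = pre_kept["bias"].to_numpy()
        post_b = post_kept["bias"].to_numpy()
        out[agg] = {
            "ttest": student_t(pre_b, post_b).as_dict(),
            "permutation": permutation_test(
                pre_b, post_b, n_iterations=n_iterations, seed=rng
            ).as_dict(),
        }
    return out
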