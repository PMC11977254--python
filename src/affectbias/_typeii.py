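"""Type II Wald chi-square ANOVA from a fitted model's coefficients.

For each fixed-effect term T a hypothesis matrix L is built so that the
Wald statistic (L b)' (L S L')^-1 (L b) tests T's coefficients adjusted
for every other term *except* T's higher-order relatives (terms whose
factor set strictly contains T's) — the marginality principle.  For a
term with no relatives L simply selects T's coefficient rows; for a term
with relatives, L spans the part of the relatives+term row space that is
orthogonal (in the coefficient-covariance inner product) to the relatives'
rows.  With sum-to-zero contrasts this reproduces the Type II Wald tests
used for mixed models in the applied literature; df = rank(L) and the
p-value is the upper tail of chi-square(df).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["type2_wald_table"]


def _conj_comp(X: np.ndarray, Z: np.ndarray, ip: np.ndarray) -> np.ndarray:
    """Basis (columns) of the complement of span(X) within span(Z), under
    the inner product matrix ``ip``."""
    A = Z.T @ ip @ X
    q, r, _ = linalg.qr(A, pivoting=True)
    diag = np.abs(np.diag(r)) if r.size else np.array([])
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank == 0:
        return Z
    return Z @ q[:, rank:]


def _term_name(term) -> str:
    names = [f.name() for f in term.factors]
    return ":".join(names) if names else "Intercept"


def _pretty(name: str) -> str:
    # C(valence, Sum) -> valence, for readable tables
    out = name
    for raw in list(_extract_c_args(name)):
        out = out.replace(raw[0], raw[1])
    return out


def _extract_c_args(name: str):
    import re

    for m in re.finditer(r"C\(([A-Za-z_][A-Za-z0-9_]*)[^)]*\)", name):
        yield m.group(0), m.group(1)


def type2_wald_table(
    params: np.ndarray,
    cov: np.ndarray,
    design_info,
    skip_intercept: bool = True,
) -> pd.DataFrame:
    """Type II Wald chi-square test per fixed-effect term.

    Parameters
    ----------
    params, cov
        Fixed-effect estimates and their covariance matrix (aligned with
        the design columns).
    design_info
        The patsy DesignInfo of the fixed-effects design (provides terms,
        their column slices and factor composition).

    Returns a DataFrame with columns ``term, chisq, df, p``.
    """
    beta = np.asarray(params, float).ravel()
    sigma = np.asarray(cov, float)
    p = beta.size
    if sigma.shape != (p, p):
        raise ValueError("covariance shape does not match coefficient vector")
    eye = np.eye(p)

    terms = list(design_info.terms)
    slices = design_info.term_slices
    factor_sets = {t: frozenset(f.name() for f in t.factors) for t in terms}

    rows = []
    for term in terms:
        fs = factor_sets[term]
        if not fs and skip_intercept:
            continue
        term_cols = list(range(*slices[term].indices(p)))
        rel_cols: list[int] = []
        for other in terms:
            if other is not term and fs and fs < factor_sets[other]:
                rel_cols.extend(range(*slices[other].indices(p)))

        h2 = eye[rel_cols + term_cols, :]
        if not rel_cols:
            L = h2
        else:
            h1 = eye[rel_cols, :]
            L = _conj_comp(h1.T, h2.T, sigma).T
            L = L[~np.all(np.abs(L) < 1e-12, axis=1)]

        lb = L @ beta
        lsl = L @ sigma @ L.T
        df = np.linalg.matrix_rank(lsl)
        if df == 0:
            raise np.linalg.LinAlgError(f"hypothesis matrix for {_term_name(term)} is null")
        try:
            chisq = float(lb @ linalg.solve(lsl, lb, assume_a="pos"))
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular hypothesis covariance for term {_term_name(term)}"
            ) from err
        rows.append(
            {
                "term": _pretty(_term_name(term)),
                "chisq": max(chisq, 0.0),
                "df": int(df),
                "p": float(stats.chi2.sf(max(chisq, 0.0), df)),
            }
        )
    return pd.DataFrame(rows)
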