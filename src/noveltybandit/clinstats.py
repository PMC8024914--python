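"""Clinical statistics: transforms, dependent-correlation tests, moderation.

Covers the subject-level statistical toolkit: rank-based inverse-normal
(Rankit) transform for skewed symptom scores, z-scoring, partial
correlation, Steiger's z for comparing dependent correlations, variance
inflation factors, OLS moderation with Johnson-Neyman regions of
significance, and the two-level (explore/non-explore) group ANCOVA on
RPE-modulated responses implemented as its mean/difference decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModerationResult",
    "group_ancova",
    "moderation_jn",
    "partial_correlation",
    "rankit_transform",
    "steiger_z",
    "vif",
    "zscore",
]

#: Rank offsets for the supported normal-scores variants.
_RANKIT_VARIANTS: dict[str, tuple[float, float]] = {
    # name: (a, b) with p_i = (r_i - a) / (n + b)
    "rankit": (0.5, 0.0),
    "blom": (0.375, 0.25),
    "tukey": (1.0 / 3.0, 1.0 / 3.0),
}


def rankit_transform(scores: np.ndarray, variant: str = "rankit") -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5)/n) by default.

    Ties receive averaged ranks; missing values pass through untouched and
    do not contribute to ``n``.  The classical Rankit offset is the default;
    ``blom`` and ``tukey`` variants are provided for sensitivity checks.
    An all-constant input maps to all zeros with a warning.
    """
    if variant not in _RANKIT_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    a, b = _RANKIT_VARIANTS[variant]
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape, np.nan)
    mask = np.isfinite(scores)
    vals = scores[mask]
    n = vals.size
    if n == 0:
        return out
    if n == 1 or np.ptp(vals) == 0:
        warnings.warn("rankit_transform of a constant input is all zeros", stacklevel=2)
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(vals, method="average")
    out[mask] = stats.norm.ppf((ranks - a) / (n + b))
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (ddof=1) over non-missing entries."""
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x)
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    out = np.full(x.shape, np.nan)
    out[mask] = (x[mask] - mu) / sd
    return out


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, Z] by least squares."""
    X = np.column_stack([np.ones(v.shape[0]), Z])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[float, int, float]:
    """Pearson correlation of x and y after removing covariates.

    Both variables are regressed on the covariates (plus intercept); the
    residual correlation is returned with df = n - 2 - k and a two-sided
    p-value from the t transform.  With no covariates this is the
    zero-order correlation with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    if k:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Z]))
        if rank < k + 1:
            raise ValueError("collinear covariates: design matrix is rank deficient")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing variable 1.

    Compares r12 with r13 given their overlap r23 using Fisher-z
    differences with the Dunn & Clark covariance correction; returns the
    z statistic and two-sided p-value.
    """
    for r in (r12, r13, r23):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rm2 = (r12**2 + r13**2) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 - R^2_j | others).

    Each column is regressed on the remaining columns plus an intercept.
    Perfectly collinear columns yield ``inf``.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D design with >= 2 columns")
    n, k = X.shape
    if n <= k:
        raise ValueError("need more rows than columns")
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        Zj = np.delete(X, j, axis=1)
        res = _residualize(yj, Zj)
        ss_res = float(res @ res)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"column {j} is constant")
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class ModerationResult:
    """Moderated OLS with Johnson-Neyman regions of significance.

    ``boundaries`` holds the 0, 1 or 2 real moderator values at which the
    simple slope of the focal predictor crosses the alpha-level critical t;
    ``significant_between`` states whether the slope is significant inside
    the interval between two boundaries (else outside / on one side).
    ``simple_slope(m)`` evaluates slope, SE, t and two-sided p at any
    moderator value.
    """

    params: pd.Series
    df_resid: int
    alpha_level: float
    boundaries: tuple[float, ...]
    significant_between: bool | None
    whole_range: str | None
    simple_slope: Callable[[float], tuple[float, float, float, float]]

    @property
    def jn_lower(self) -> float:
        return self.boundaries[0] if self.boundaries else float("nan")

    @property
    def jn_upper(self) -> float:
        return self.boundaries[-1] if len(self.boundaries) >= 2 else float("nan")


def moderation_jn(
    outcome: np.ndarray,
    x: np.ndarray,
    moderator: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha_level: float = 0.05,
) -> ModerationResult:
    """Fit ``y ~ x * moderator + covariates`` and locate JN boundaries.

    The simple slope of x at moderator value m is b_x + b_int * m with
    variance v_xx + 2 m v_x,int + m^2 v_int,int; Johnson-Neyman boundaries
    are the real roots of the quadratic where its t statistic equals the
    two-sided critical t at ``alpha_level``.  With no real roots the whole
    moderator range is uniformly significant or nonsignificant, reported in
    ``whole_range``.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(moderator, dtype=float)
    n = y.size
    cols = {"x": x, "moderator": m, "x_x_moderator": x * m}
    if covariates is not None and np.asarray(covariates).size:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        for j in range(Z.shape[1]):
            cols[f"cov{j}"] = Z[:, j]
    if n <= len(cols) + 2:
        raise ValueError("too few observations for the moderation model")

    X = np.column_stack([np.ones(n), *cols.values()])
    names = ["const", *cols.keys()]
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient moderation design")
    resid = y - X @ coef
    df_resid = n - X.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)

    i_x, i_int = names.index("x"), names.index("x_x_moderator")
    b1, b3 = coef[i_x], coef[i_int]
    v11, v13, v33 = cov[i_x, i_x], cov[i_x, i_int], cov[i_int, i_int]
    t_crit = stats.t.ppf(1 - alpha_level / 2, df_resid)

    def simple_slope(mv: float) -> tuple[float, float, float, float]:
        slope = b1 + b3 * mv
        se = float(np.sqrt(v11 + 2 * mv * v13 + mv**2 * v33))
        t = slope / se
        return float(slope), se, float(t), float(2 * stats.t.sf(abs(t), df_resid))

    a = b3**2 - t_crit**2 * v33
    b = 2 * (b1 * b3 - t_crit**2 * v13)
    c = b1**2 - t_crit**2 * v11
    disc = b**2 - 4 * a * c

    boundaries: tuple[float, ...] = ()
    significant_between: bool | None = None
    whole_range: str | None = None
    if a == 0 and b == 0:
        whole_range = "significant" if c > 0 else "nonsignificant"
    elif a == 0:
        boundaries = (float(-c / b),)
    elif disc < 0:
        # no real crossing: the t^2 curve never meets the critical line
        mid_p = simple_slope(float(np.mean(m)))[3]
        whole_range = "significant" if mid_p < alpha_level else "nonsignificant"
    else:
        r1 = (-b - np.sqrt(disc)) / (2 * a)
        r2 = (-b + np.sqrt(disc)) / (2 * a)
        lo, hi = sorted((float(r1), float(r2)))
        boundaries = (lo, hi)
        significant_between = simple_slope((lo + hi) / 2)[3] < alpha_level

    return ModerationResult(
        params=pd.Series(coef, index=names),
        df_resid=df_resid,
        alpha_level=alpha_level,
        boundaries=boundaries,
        significant_between=significant_between,
        whole_range=whole_range,
        simple_slope=simple_slope,
    )


def _ols_term_tests(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Per-term F (= t^2), partial eta^2 and p for an OLS with intercept."""
    n = y.size
    M = np.column_stack([np.ones(n), X.to_numpy(float)])
    coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    resid = y - M @ coef
    df_resid = n - M.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    if sigma2 == 0.0:
        # exactly fitted outcome (e.g. identically zero difference): report
        # null effects rather than 0/0
        sigma2 = np.finfo(float).tiny
    cov = sigma2 * np.linalg.inv(M.T @ M)
    rows = []
    for j, name in enumerate(X.columns, start=1):
        t2 = coef[j] ** 2 / cov[j, j]
        rows.append(
            {
                "term": name,
                "F": float(t2),
                "df1": 1,
                "df2": df_resid,
                "partial_eta_sq": float(t2 / (t2 + df_resid)),
                "p": float(stats.f.sf(t2, 1, df_resid)),
            }
        )
    return pd.DataFrame(rows)


def group_ancova(
    cohort: pd.DataFrame,
    beta_explore_col: str = "roi_beta_explore",
    beta_nonexplore_col: str = "roi_beta_nonexplore",
    predictor_cols: Sequence[str] = ("audit_rankit_z", "cudit_z", "np_z", "sex"),
    interaction_pairs: Sequence[tuple[str, str]] = (
        ("audit_rankit_z", "np_z"),
        ("cudit_z", "np_z"),
    ),
) -> pd.DataFrame:
    """Two-level (explore / non-explore) ANCOVA on RPE-modulated betas.

    Implemented as the mean/difference decomposition, algebraically
    equivalent to a mixed-design ANCOVA with a two-level within factor:
    between-subject effects are tested on the subject mean of the two
    betas, and each predictor's interaction with the Decision factor on
    their difference (explore - non-explore).  Subjects missing either beta
    are excluded listwise (count in the ``n_excluded`` attribute of the
    returned frame).  Returns term, effect type, F, partial eta^2, p.
    """
    needed = [beta_explore_col, beta_nonexplore_col, *predictor_cols]
    for a_col, b_col in interaction_pairs:
        needed += [a_col, b_col]
    needed = list(dict.fromkeys(needed))
    sub = cohort[needed].dropna()
    n_excluded = len(cohort) - len(sub)
    if len(sub) < len(predictor_cols) + len(interaction_pairs) + 3:
        raise ValueError("too few complete cases for the ANCOVA")

    X = sub[list(predictor_cols)].astype(float).copy()
    for a_col, b_col in interaction_pairs:
        X[f"{a_col}_x_{b_col}"] = sub[a_col].astype(float) * sub[b_col].astype(float)

    be = sub[beta_explore_col].to_numpy(float)
    bn = sub[beta_nonexplore_col].to_numpy(float)
    between = _ols_term_tests((be + bn) / 2.0, X)
    between.insert(1, "effect", "between")
    decision = _ols_term_tests(be - bn, X)
    decision.insert(1, "effect", "decision_interaction")
    decision["term"] = decision["term"] + "_x_decision"

    out = pd.concat([between, decision], ignore_index=True)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["n_used"] = len(sub)
    return out
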