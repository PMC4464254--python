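"""Group-level inference: correlations, partial correlation, Sobel mediation.

All p-values are two-tailed.  Correlation reports carry the sample size and
the exact Bonferroni-adjusted alpha used, so significance flags are always
recomputable from (p, adjusted alpha).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclasses.dataclass(frozen=True)
class CorrelationReport:
    r: float
    p: float
    n: int
    adjusted_alpha: float
    significant: bool
    kind: str = "pearson"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class MediationReport:
    """Sobel test of the indirect effect X -> M -> Y.

    ``a`` is the X->M slope, ``b`` the M->Y slope controlling for X;
    z = a*b / sqrt(b^2 SEa^2 + a^2 SEb^2) with a two-tailed normal p.
    """

    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float
    sobel_z: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y, alpha: float = 0.05, n_tests: int = 1) -> CorrelationReport:
    """Product-moment correlation with a two-tailed t-based p-value."""
    x, y = _validate_xy(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    adj = bonferroni_alpha(alpha, n_tests)
    return CorrelationReport(
        r=float(res.statistic),
        p=float(res.pvalue),
        n=len(x),
        adjusted_alpha=adj,
        significant=bool(res.pvalue < adj),
    )


def partial_correlation(x, y, z, alpha: float = 0.05, n_tests: int = 1) -> CorrelationReport:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    tested on n - 3 degrees of freedom; equivalent to the Pearson
    correlation of the two z-residualised vectors.
    """
    x, y = _validate_xy(x, y, 4)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("covariate must match x and y in length")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("covariate is collinear with x or y; partial correlation degenerate")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    n = len(x)
    df = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    adj = bonferroni_alpha(alpha, n_tests)
    return CorrelationReport(
        r=r, p=p, n=n, adjusted_alpha=adj, significant=bool(p < adj), kind="partial"
    )


def sobel_mediation(x, m, y) -> MediationReport:
    """Sobel test of mediation along the chain x -> m -> y.

    Path a: OLS of m on x.  Path b: OLS of y on m controlling for x.
    The normal-theory Sobel z is known to be conservative at small n.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be 1-D vectors of equal length")
    n = len(x)
    if n < 5:
        raise ValueError("mediation needs at least 5 observations")
    Xa = sm.add_constant(x)
    if np.linalg.matrix_rank(Xa) < 2:
        raise ValueError("x is constant; paths not estimable")
    fit_a = sm.OLS(m, Xa).fit()
    a, se_a = float(fit_a.params[1]), float(fit_a.bse[1])
    Xb = sm.add_constant(np.column_stack([m, x]))
    if np.linalg.matrix_rank(Xb) < 3:
        raise ValueError("m and x are collinear; path b not estimable")
    fit_b = sm.OLS(y, Xb).fit()
    b, se_b = float(fit_b.params[1]), float(fit_b.bse[1])
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    z = 0.0 if denom == 0 else a * b / denom
    p = float(2 * stats.norm.sf(abs(z)))
    return MediationReport(
        a=a, se_a=se_a, b=b, se_b=se_b, indirect=a * b, sobel_z=float(z), p=p, n=n
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise alpha divided by the number of tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m
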