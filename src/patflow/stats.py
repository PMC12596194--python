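"""Cohort statistics: TOST equivalence, Spearman correlation, concurrence
rate, linear regression with confounder adjustment, and one-way ANOVA.

The primary analysis is paired equivalence testing (TOST) of the inverted
PAT change (iCPAT, ms) against the BP change (mmHg) between hour periods,
under the working assumption that a 1-ms PAT change corresponds to ~1 mmHg
of BP change, with a predefined equivalence margin of +/-5 mmHg.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as ss

__all__ = [
    "TOSTResult",
    "tost_paired",
    "spearman",
    "CCRResult",
    "concurrence_rate",
    "RegressionResult",
    "ols_regression",
    "oneway_anova",
]


@dataclass
class TOSTResult:
    """Two one-sided t-tests on paired differences against a +/-margin band."""

    n: int
    mean_diff: float
    sd_diff: float
    margin: float
    alpha: float
    p1: float  # H0: mean <= -margin
    p2: float  # H0: mean >= +margin

    @property
    def equivalent(self) -> bool:
        return max(self.p1, self.p2) < self.alpha


def tost_paired(
    icpat: np.ndarray,
    d_bp: np.ndarray,
    margin: float = 5.0,
    alpha: float = 0.05,
) -> TOSTResult:
    """TOST equivalence of paired iCPAT (ms) and BP change (mmHg) observations.

    Tests whether the mean paired difference ``d = icpat - d_bp`` lies within
    ``(-margin, +margin)``:

    * ``p1 = P(T_{n-1} > (mean(d)+margin) / (sd/sqrt(n)))`` against
      ``mean <= -margin``,
    * ``p2 = P(T_{n-1} < (mean(d)-margin) / (sd/sqrt(n)))`` against
      ``mean >= +margin``;

    equivalence is declared iff both one-sided p-values are below ``alpha``.
    A zero-variance sample is a point mass: p-values are 0 on each side whose
    boundary the mean strictly clears, 1 otherwise.
    """
    icpat = np.asarray(icpat, dtype=float)
    d_bp = np.asarray(d_bp, dtype=float)
    if icpat.shape != d_bp.shape:
        raise ValueError("icpat and d_bp must be paired (equal length)")
    n = icpat.size
    if n < 3:
        raise ValueError("TOST requires n >= 3 paired observations")
    d = icpat - d_bp
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p1 = 0.0 if mean > -margin else 1.0
        p2 = 0.0 if mean < margin else 1.0
    else:
        se = sd / np.sqrt(n)
        p1 = float(ss.t.sf((mean + margin) / se, df=n - 1))
        p2 = float(ss.t.cdf((mean - margin) / se, df=n - 1))
    return TOSTResult(
        n=n, mean_diff=mean, sd_diff=sd, margin=margin, alpha=alpha, p1=p1, p2=p2
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value over all orderings of y (n <= 10)."""
    n = x.size
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c**2))
    count = 0
    total = 0
    chunk: list[np.ndarray] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(ry[list(perm)])
        if len(chunk) == 20000:
            count, total = _spearman_chunk(np.array(chunk), rx_c, denom, rho_obs, count, total)
            chunk = []
    if chunk:
        count, total = _spearman_chunk(np.array(chunk), rx_c, denom, rho_obs, count, total)
    return count / total


def _spearman_chunk(perms, rx_c, denom, rho_obs, count, total):
    ry_c = perms - perms.mean(axis=1, keepdims=True)
    denys = np.sqrt(np.sum(ry_c**2, axis=1))
    rhos = (ry_c @ rx_c) / (denom * denys)
    count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    total += perms.shape[0]
    return count, total


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` (``method='t'``, adequate for the
    cohort sizes this pipeline targets); ``method='exact'`` computes a
    permutation p-value (n <= 10 only).  ``rho = +/-1`` yields p = 0; a
    constant input leaves rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = ss.spearmanr(x, y)
    rho = float(rho)
    if method == "exact":
        if x.size > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        return rho, float(_spearman_exact_p(x, y, rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    return rho, float(p)


@dataclass
class CCRResult:
    """Concurrence rate: fraction of observations with opposite-signed changes."""

    n_total: int
    n_opposite: int
    subgroup: str = "all"

    @property
    def ccr(self) -> float:
        return self.n_opposite / self.n_total


def concurrence_rate(
    d_pat: np.ndarray,
    d_bp: np.ndarray,
    subgroup_mask: np.ndarray | None = None,
    subgroup: str = "all",
    drop_zeros: bool = False,
) -> CCRResult:
    """Ratio of opposite-signed PAT/BP changes to all observations.

    Opposite means ``sign(d_pat) * sign(d_bp) == -1`` (PAT up while BP down,
    or vice versa — the agreeing behaviour under the inverse relationship).
    Exact-zero changes stay in the denominator but never count as opposite;
    ``drop_zeros=True`` removes them from the denominator as a sensitivity
    option.  ``subgroup_mask`` restricts the computation (e.g. to BP risers
    and decliners only).
    """
    d_pat = np.asarray(d_pat, dtype=float)
    d_bp = np.asarray(d_bp, dtype=float)
    if d_pat.shape != d_bp.shape:
        raise ValueError("d_pat and d_bp must have equal length")
    if subgroup_mask is not None:
        d_pat = d_pat[subgroup_mask]
        d_bp = d_bp[subgroup_mask]
    if drop_zeros:
        keep = (np.sign(d_pat) != 0) & (np.sign(d_bp) != 0)
        d_pat, d_bp = d_pat[keep], d_bp[keep]
    if d_pat.size == 0:
        raise ValueError("concurrence rate undefined on empty input")
    opposite = np.sign(d_pat) * np.sign(d_bp) == -1
    return CCRResult(
        n_total=int(d_pat.size), n_opposite=int(np.sum(opposite)), subgroup=subgroup
    )


@dataclass
class RegressionResult:
    """OLS fit summary: per-predictor coefficient, SE, t and p."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    model_type: str
    n: int
    r_squared: float


def ols_regression(
    response: np.ndarray,
    predictors: pd.DataFrame,
    model_type: str = "univariate",
) -> RegressionResult:
    """Ordinary least squares with intercept.

    Coefficients solve the normal equations; standard errors come from
    ``sigma^2 (X'X)^{-1}`` and two-sided p-values from ``t_{n-p}``.  A
    rank-deficient design is rejected with the offending columns named.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    if y.size != len(X):
        raise ValueError("response and predictors must have equal length")
    design = sm.add_constant(X, has_constant="add")
    if y.size <= design.shape[1]:
        raise ValueError("need n > number of predictors (incl. intercept)")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = []
        kept: list[str] = []
        for col in design.columns:
            trial = design[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        model_type=model_type,
        n=int(y.size),
        r_squared=float(fit.rsquared),
    )


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F-test over >= 2 groups (each n >= 2).

    Uses the between/within sum-of-squares decomposition with
    ``F = (SSB/(k-1)) / (SSW/(N-k))`` and the F tail probability.  Identical
    groups (no between-group variation) give ``F = 0, p = 1`` even when the
    within-group variance is zero.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    k = len(arrs)
    n_tot = all_vals.size
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n_tot - k))
    p = float(ss.f.sf(f, k - 1, n_tot - k))
    return float(f), p
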