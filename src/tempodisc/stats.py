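"""Inferential procedures for linking timing to discounting.

Pearson correlations with exact t-based p-values, total-least-squares (TLS)
lines for scatter with error in both variables, label-shuffling permutation
tests of group mean differences, drop-one likelihood-ratio regressions (each
predictor removed in turn from a Gaussian linear model and the likelihood
drop tested by chi-square, reported alongside the AIC change), the
Dunn-Clark z test comparing two dependent correlations that share no
variable, and the Fisher-z power analysis for a correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TLSLine",
    "PermutationResult",
    "CorrComparisonResult",
    "pearson_correlation",
    "tls_fit",
    "permutation_mean_difference",
    "drop_one_regression",
    "compare_nonoverlapping_dependent_correlations",
    "required_sample_size_for_correlation",
]


def _clean_xy(x, y, min_n: int = 2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with the exact two-sided t-test p-value."""
    x, y = _clean_xy(x, y, min_n=3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TLSLine:
    """Line minimising summed squared orthogonal distances (first principal
    axis of the centred scatter)."""

    slope: float
    intercept: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def tls_fit(x, y) -> TLSLine:
    """Total-least-squares line through a 2-d scatter.

    Unlike ordinary regression, the TLS line treats x and y symmetrically:
    swapping the axes maps the slope m to 1/m.  Undefined when all points
    coincide or the principal axis is vertical.
    """
    x, y = _clean_xy(x, y, min_n=2)
    xc, yc = x - x.mean(), y - y.mean()
    if np.all(xc == 0) and np.all(yc == 0):
        raise ValueError("all points identical; TLS line undefined")
    # principal axis via SVD of the centred data matrix
    _, _, vt = np.linalg.svd(np.column_stack([xc, yc]), full_matrices=False)
    vx, vy = vt[0]
    if abs(vx) < 1e-12:
        raise ValueError("principal axis is vertical; slope undefined")
    slope = float(vy / vx)
    return TLSLine(slope=slope, intercept=float(y.mean() - slope * x.mean()))


@dataclass
class PermutationResult:
    """Label-shuffling test of a difference in group means."""

    observed_diff: float
    p_value: float
    n_shuffles: int
    seed: int


def permutation_mean_difference(
    group_a, group_b, n_shuffles: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Two-sided permutation test of mean(group_a) - mean(group_b).

    The group labels are shuffled ``n_shuffles`` times over the pooled
    sample, building a null distribution of |mean difference|; the p-value
    uses add-one smoothing, (1 + #{|null| >= |observed|}) / (n_shuffles + 1),
    so it is always positive.  The null draws depend only on the pooled
    values and the two group sizes, so relabelling the groups gives the same
    p-value under the same seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    observed = float(a.mean() - b.mean())
    # canonical pooled ordering => label-order invariance under a fixed seed
    pooled = np.sort(np.concatenate([a, b]))
    n_small = min(len(a), len(b))
    total = pooled.sum()
    n_tot = len(pooled)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        pick = rng.permutation(n_tot)[:n_small]
        m_small = pooled[pick].mean()
        m_large = (total - pooled[pick].sum()) / (n_tot - n_small)
        null[i] = abs(m_small - m_large)
    p = (1.0 + np.sum(null >= abs(observed))) / (n_shuffles + 1.0)
    return PermutationResult(
        observed_diff=observed, p_value=float(p), n_shuffles=n_shuffles, seed=seed
    )


def drop_one_regression(
    response,
    predictors: pd.DataFrame,
    bonferroni_m: int = 4,
) -> pd.DataFrame:
    """Drop-one likelihood-ratio analysis of a Gaussian linear model.

    Fits response ~ all predictors (+ intercept) by maximum likelihood, then
    refits with each predictor removed in turn.  For each dropped term,
    reports the chi-square likelihood-ratio statistic (df=1), its p-value,
    the AIC change (AIC_reduced - AIC_full; negative means the model improves
    when the term is dropped), and significance at the Bonferroni-corrected
    threshold .05 / ``bonferroni_m``.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than parameters")
    mat = np.column_stack([np.ones(n), X.to_numpy()])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        pairs = [
            (X.columns[i], X.columns[j])
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"exact collinearity among predictors: {pairs or list(X.columns)}")
    full = sm.OLS(y, sm.add_constant(X)).fit()
    rows = []
    threshold = 0.05 / bonferroni_m
    for term in X.columns:
        reduced = sm.OLS(y, sm.add_constant(X.drop(columns=[term]))).fit()
        lr = max(0.0, 2.0 * (full.llf - reduced.llf))
        pval = float(sps.chi2.sf(lr, df=1))
        rows.append({
            "dropped": term,
            "lr_chi2": float(lr),
            "df": 1,
            "p": pval,
            "delta_aic": float(reduced.aic - full.aic),
            "significant": bool(pval < threshold),
        })
    return pd.DataFrame(rows)


@dataclass
class CorrComparisonResult:
    """Dunn-Clark comparison of two dependent, nonoverlapping correlations."""

    r_baseline: float
    r_alternative: float
    z: float
    p_value: float            # two-sided
    p_one_sided: float        # H1: r_alternative > r_baseline
    significant: bool         # two-sided at .05


def compare_nonoverlapping_dependent_correlations(
    r12: float,
    r34: float,
    pairwise_rs: dict,
    n: int,
    alpha: float = 0.05,
) -> CorrComparisonResult:
    """Test whether corr(1,2) differs from corr(3,4) on the same n subjects.

    The four variables share no member across the two correlations, but are
    measured on the same sample, so the correlations are dependent; the
    Dunn & Clark (1969) z statistic compares their Fisher transforms with a
    covariance determined by the six pairwise correlations.  ``pairwise_rs``
    supplies r13, r14, r23, r24.
    """
    r13, r14 = float(pairwise_rs["r13"]), float(pairwise_rs["r14"])
    r23, r24 = float(pairwise_rs["r23"]), float(pairwise_rs["r24"])
    r12, r34 = float(r12), float(r34)
    R = np.array([
        [1.0, r12, r13, r14],
        [r12, 1.0, r23, r24],
        [r13, r23, 1.0, r34],
        [r14, r24, r34, 1.0],
    ])
    if np.any(np.abs(R) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("pairwise correlations are not positive semi-definite")
    if n < 5:
        raise ValueError("need n >= 5")
    cov = (
        0.5 * r12 * r34 * (r13 ** 2 + r14 ** 2 + r23 ** 2 + r24 ** 2)
        + r13 * r24 + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r13 * r23 * r34 + r14 * r24 * r34)
    )
    c = cov / ((1.0 - r12 ** 2) * (1.0 - r34 ** 2))
    dz = np.arctanh(r12) - np.arctanh(r34)
    z = float(dz * np.sqrt((n - 3) / max(2.0 - 2.0 * c, 1e-12)))
    p_two = float(2.0 * sps.norm.sf(abs(z)))
    # one-sided: is the alternative correlation (r34) larger than the baseline?
    p_one = float(sps.norm.cdf(z))
    return CorrComparisonResult(
        r_baseline=r12,
        r_alternative=r34,
        z=z,
        p_value=min(p_two, 1.0),
        p_one_sided=p_one,
        significant=bool(p_two < alpha),
    )


def _correlation_power(n: int, r: float, alpha: float) -> float:
    """Power of the two-sided Fisher-z test of H0: rho = 0 at sample size n,
    with the small-sample bias term r / (2 (n - 1)) added to atanh(r)."""
    if n < 4:
        return 0.0
    mean = (np.arctanh(r) + r / (2.0 * (n - 1.0))) * np.sqrt(n - 3.0)
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.sf(z_crit - mean) + sps.norm.cdf(-z_crit - mean))


def required_sample_size_for_correlation(
    r: float, power: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest n whose two-sided Fisher-z test of a correlation of size r
    reaches the target power.

    Uses the normal approximation to the Fisher transform: the test statistic
    has mean sqrt(n-3) * (atanh(r) + r / (2(n-1))) and unit variance.
    """
    r = abs(float(r))
    if not 0.0 < r < 1.0:
        raise ValueError("need 0 < |r| < 1")
    if not 0.0 < power < 1.0:
        raise ValueError("need 0 < power < 1")
    for n in range(4, 10_000_000):
        if _correlation_power(n, r, alpha) >= power:
            return n
    raise RuntimeError("no attainable sample size")  # pragma: no cover
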