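"""Cohort-level statistics: summaries, rank correlations, Loess, agreement.

This layer mirrors how clinical T2* cohorts are usually reported: a
descriptive table (mean +- SD, median, range, category counts with
percentages), Spearman rank correlations between organ T2* values and
serum ferritin with a verbal magnitude label, a Loess-smoothed scatter
trend, and paired method-agreement statistics (mean difference with a
paired-t confidence interval) when two software routes measure the same
organ.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "CorrelationResult", "AgreementResult", "SummaryTable",
    "spearman", "classify_magnitude", "loess_smooth", "method_agreement",
    "summarize_cohort", "stratified_spearman", "percentage",
]

logger = logging.getLogger(__name__)

#: magnitude bands on |r|: weak < 0.4 <= moderate <= 0.6 < strong.
#: 0.4 and 0.6 are counted as moderate (band edges inclusive).
MAGNITUDE_BANDS = (0.4, 0.6)


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage rounded half away from zero to ``ndigits`` decimals.

    Uses decimal arithmetic, so e.g. 32/39 -> 82.1 and 9/39 -> 23.1
    independent of binary float ties.
    """
    if total <= 0:
        raise InvalidInputError("total must be positive")
    q = Decimal(10) ** -ndigits
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its verbal magnitude label."""

    r: float
    p_value: float
    n: int
    magnitude: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise InvalidInputError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise InsufficientDataError("correlation needs n >= 3")


def classify_magnitude(r: float) -> str:
    """Label |r|: 'weak' below 0.4, 'moderate' in [0.4, 0.6], 'strong' above.

    The label follows |r|; direction is carried by the sign of r itself.
    """
    r = float(r)
    if abs(r) > 1 + 1e-12:
        raise InvalidInputError(f"|r| must be <= 1, got {r}")
    lo, hi = MAGNITUDE_BANDS
    a = abs(r)
    if a < lo:
        return "weak"
    if a <= hi:
        return "moderate"
    return "strong"


def _pairwise_complete(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equally long")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(x.size - keep.sum())
    if dropped:
        logger.info("spearman: dropped %d incomplete pairs", dropped)
    return x[keep], y[keep]


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    r is the Pearson correlation of average ranks (ties get average
    ranks); the two-sided p-value uses the t approximation with n - 2
    degrees of freedom.  With ``exact=True`` (allowed for n <= 10) the
    p-value is instead computed by full enumeration of the n! pairings.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs after missing-value removal, got {n}"
        )
    r, p = stats.spearmanr(x, y)
    r = float(r)
    if exact:
        if n > 10:
            raise InvalidInputError("exact permutation p only supported for n <= 10")
        p = _exact_spearman_p(x, y, r)
    return CorrelationResult(r=r, p_value=float(p), n=n,
                             magnitude=classify_magnitude(r))


def _exact_spearman_p(x, y, r_obs: float) -> float:
    """Two-sided permutation p by enumerating all pairings of y against x."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = ry - ry.mean()
    denom = np.sqrt((ry ** 2).sum() * len(ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r_perm = float(np.dot(rx, perm)) / denom
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def stratified_spearman(x, y, strata, min_n: int = 3,
                        exact: bool = False) -> dict:
    """Spearman within each stratum; strata below ``min_n`` pairs are
    skipped with a log warning.

    Returns a dict mapping stratum label to :class:`CorrelationResult`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    strata = np.asarray(strata)
    if not (x.shape == y.shape == strata.shape):
        raise InvalidInputError("x, y and strata must be equally long")
    out = {}
    for label in pd.unique(strata):
        sel = strata == label
        try:
            out[label] = spearman(x[sel], y[sel], exact=exact)
        except InsufficientDataError:
            logger.warning("stratum %r has fewer than %d complete pairs; "
                           "skipped", label, min_n)
    return out


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

def loess_smooth(x, y, span: float = 0.75):
    """Locally weighted linear regression (Loess, degree 1, tricube).

    For each point, the ``k = floor(span * n)`` nearest neighbours in x
    define the local window; tricube weights ``(1 - (d/h)^3)^3`` with h the
    window radius feed a weighted straight-line fit evaluated at that
    point.  No robustness iterations are applied.  Deterministic for fixed
    inputs.

    Parameters
    ----------
    x, y : 1-D arrays, n >= 5
    span : float in (0, 1]
        Fraction of the data in each local window.

    Returns
    -------
    (x_sorted, fitted) : two 1-D arrays
        Fitted values at the sorted x positions.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equally long")
    n = x.size
    if n < 5:
        raise InsufficientDataError("loess needs n >= 5")
    if not 0 < span <= 1:
        raise InvalidInputError("span must be in (0, 1]")
    k = int(span * n)
    if k < 2:
        raise InsufficientDataError(
            f"span {span} gives a {k}-point window at n = {n}; too small"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            # >= k duplicates at this x: average them
            fitted[i] = ys[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            fitted[i] = ym
        else:
            beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
            fitted[i] = ym + beta * (xs[i] - xm)
    return xs, fitted


# ---------------------------------------------------------------------------
# Method agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Paired mean difference (a - b) with a two-sided t confidence interval."""

    mean_difference: float
    ci_low: float
    ci_high: float
    confidence: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise InvalidInputError("CI must bracket the mean difference")


def method_agreement(a, b, confidence: float = 0.95) -> AgreementResult:
    """Mean of paired differences a - b with a paired-t CI.

    Zero-variance differences give a degenerate CI equal to the mean.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("a and b must be 1-D and equally long")
    keep = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[keep]
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired agreement needs n >= 2 pairs")
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return AgreementResult(m, m, m, confidence, n)
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n)
    return AgreementResult(m, m - half, m + half, confidence, n)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryTable:
    """Descriptive cohort summary.

    ``continuous`` has one row per numeric variable (mean, sd, median,
    min, max); ``categorical`` has one row per (variable, level) with
    count and percentage of non-missing values, percentages rounded half
    away from zero to one decimal.
    """

    continuous: pd.DataFrame
    categorical: pd.DataFrame
    n: int

    def to_csv(self, cont_path, cat_path) -> None:
        self.continuous.to_csv(cont_path)
        self.categorical.to_csv(cat_path, index=False)


def summarize_cohort(cohort: pd.DataFrame,
                     exclude: tuple = ("patient_id",)) -> SummaryTable:
    """Table-style descriptive summary of a (graded) cohort.

    Continuous variables use the n-1 SD denominator (SD = 0 for a single
    observation); categorical counts are over non-missing entries per
    variable.  Rows with a missing value only drop out of that variable's
    row (listwise within the row).
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    cont_rows = {}
    cat_rows = []
    for col in cohort.columns:
        if col in exclude:
            continue
        series = cohort[col]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.dropna().astype(float)
            if len(vals) == 0:
                continue
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            cont_rows[col] = {
                "n": len(vals), "mean": float(vals.mean()), "sd": sd,
                "median": float(vals.median()),
                "min": float(vals.min()), "max": float(vals.max()),
            }
        else:
            vals = series.dropna()
            total = len(vals)
            if total == 0:
                continue
            for level, count in vals.value_counts().items():
                cat_rows.append({
                    "variable": col, "level": level, "count": int(count),
                    "pct": percentage(int(count), total),
                })
    return SummaryTable(
        continuous=pd.DataFrame(cont_rows).T.rename_axis("variable"),
        categorical=pd.DataFrame(
            cat_rows, columns=["variable", "level", "count", "pct"]),
        n=len(cohort),
    )


def correlation_table(cohort: pd.DataFrame, pairs) -> pd.DataFrame:
    """Spearman r / p / magnitude for a list of column pairs."""
    rows = []
    for cx, cy in pairs:
        res = spearman(cohort[cx], cohort[cy])
        rows.append({"x": cx, "y": cy, "r": res.r, "p_value": res.p_value,
                     "n": res.n, "magnitude": res.magnitude})
    return pd.DataFrame(rows)


def scatter_with_loess(x, y, span: float = 0.75, ax=None,
                       xlabel: str = "", ylabel: str = ""):
    """Scatter plot with the Loess trend line overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs, fitted = loess_smooth(x, y, span=span)
    ax.plot(x, y, "o", color="k", alpha=0.7)
    ax.plot(xs, fitted, "-", color="tab:red", lw=2, label=f"Loess (span {span})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax
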