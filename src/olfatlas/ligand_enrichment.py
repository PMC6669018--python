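"""Ligand-class enrichment statistics for highly abundant OR subtypes.

Deorphaned olfactory receptors (receptors with at least one experimentally
established ligand) can be asked whether they are over-represented among the
most abundant OSN subtypes — those above the 90th expression percentile.
Because the top-decile set is defined by the 90th percentile, the chance
baseline for membership is p0 = 0.10, and the question reduces to an exact
binomial test on k top-decile receptors out of n deorphaned ones.

This module provides the statistical primitives — a two-tailed exact binomial
test (method of small p-values), the Wilson score interval, Welch's unequal
variance t-test, and fold changes of group means — and an
:func:`enrichment_report` that combines them for one ligand class (key food
odorants, semiochemicals, or other odorants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "NoTestResult",
    "binom_two_tail",
    "wilson_interval",
    "welch_t",
    "fold_change",
    "enrichment_report",
]

#: Relative tolerance used when comparing point probabilities in the
#: two-tailed binomial test; absorbs floating-point noise in the pmf.
_PMF_RELTOL = 1e-7


def binom_two_tail(k: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p-value by the method of small p-values.

    Sums ``P(X = j | n, p0)`` over every outcome ``j`` whose point
    probability does not exceed that of the observed ``k`` (up to a relative
    tolerance of 1e-7), and caps the sum at 1. This is the dominant
    convention for two-sided exact binomial tests.

    Parameters
    ----------
    k : int
        Observed number of successes, ``0 <= k <= n``.
    n : int
        Number of trials.
    p0 : float
        Null success probability, strictly inside (0, 1).

    Returns
    -------
    float
        Two-tailed p-value in (0, 1].
    """
    k = int(k)
    n = int(n)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must satisfy 0 <= k <= n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} must lie strictly inside (0, 1)")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1.0 + _PMF_RELTOL)].sum())
    return min(1.0, p)


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    With ``p_hat = k/n`` and ``z`` the standard-normal quantile for the given
    two-sided confidence level, the interval is centred at
    ``(p_hat + z^2/2n) / (1 + z^2/n)`` with half-width
    ``z * sqrt(p_hat(1-p_hat)/n + z^2/4n^2) / (1 + z^2/n)``.

    The bounds collapse exactly to 0 at ``k = 0`` and to 1 at ``k = n``.
    """
    k = int(k)
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must satisfy 0 <= k <= n={n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p_hat = k / n
    denom = 1.0 + z * z / n
    centre = (p_hat + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n)) / denom
    low = max(0.0, centre - half)
    high = min(1.0, centre + half)
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return float(low), float(high)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns ``(t, df, p)`` with ``t = (mean(x) - mean(y)) / sqrt(sx^2/nx +
    sy^2/ny)`` and degrees of freedom by the Welch–Satterthwaite
    approximation. Sample variances use the n-1 denominator.

    When both samples are constant with equal means the statistic is taken
    as 0 with p = 1 (no evidence of a difference); constant samples with
    unequal means yield an infinite statistic and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), float(nx + ny - 2), 0.0
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 * se2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def fold_change(group_a, group_b) -> float:
    """Ratio of the arithmetic means of two groups of per-OR mean expressions.

    ``fold_change(a, b) = mean(a) / mean(b)``; the denominator must be
    positive.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    mb = b.mean()
    if mb <= 0:
        raise ValueError("denominator group mean must be positive")
    return float(a.mean() / mb)


@dataclass(frozen=True)
class NoTestResult:
    """Returned when a class has no deorphaned ORs to test."""

    class_selector: str
    reason: str


@dataclass(frozen=True)
class EnrichmentResult:
    """Top-decile enrichment summary for one ligand class.

    ``k`` of ``n`` class-positive deorphaned ORs are in the species' top
    decile; ``p_two_tail`` is the exact binomial p against baseline ``p0``;
    the Wilson interval brackets ``k/n``. ``fold_change`` and the Welch test
    compare mean normalized expression of class ORs against deorphaned
    non-class ORs (NaN when the comparison group is empty).
    """

    class_selector: str
    k: int
    n: int
    p0: float
    p_two_tail: float
    wilson_low: float
    wilson_high: float
    fold_change: float = field(default=float("nan"))
    welch_t: float = field(default=float("nan"))
    welch_df: float = field(default=float("nan"))
    welch_p: float = field(default=float("nan"))


_CLASS_SELECTORS = ("KFO", "SMC", "other", "any")


def _class_positive(pairs: pd.DataFrame, selector: str) -> pd.Index:
    """OR ids with at least one ligand pair of the selected class."""
    if selector == "KFO":
        mask = pairs["is_kfo"].astype(bool)
    elif selector == "SMC":
        mask = pairs["is_smc"].astype(bool)
    elif selector == "other":
        mask = ~(pairs["is_kfo"].astype(bool) | pairs["is_smc"].astype(bool))
    elif selector == "any":
        mask = pd.Series(True, index=pairs.index)
    else:
        raise ValueError(f"class selector must be one of {_CLASS_SELECTORS}, got {selector!r}")
    return pd.Index(pairs.loc[mask, "or_id"].unique())


def enrichment_report(
    abundance: pd.DataFrame,
    pairs: pd.DataFrame,
    class_selector: str,
    *,
    p0: float = 0.10,
    confidence: float = 0.95,
    welch_scale: str = "log10p1",
) -> EnrichmentResult | NoTestResult:
    """Test whether a ligand class is enriched among top-decile ORs.

    Parameters
    ----------
    abundance : pandas.DataFrame
        Per-OR abundance table indexed by gene id with at least columns
        ``mean_norm`` and ``top_decile`` (see ``quantify.summarize_abundance``
        / ``quantify.top_decile_set``).
    pairs : pandas.DataFrame
        OR–ligand pair table with columns ``or_id``, ``is_kfo``, ``is_smc``.
        An OR is *deorphaned* if it appears in at least one pair.
    class_selector : str
        One of ``"KFO"``, ``"SMC"``, ``"other"`` or ``"any"`` (any
        deorphaned OR).
    p0 : float
        Baseline top-decile proportion; fixed at 0.10 by the 90th-percentile
        definition rather than estimated from data.
    welch_scale : str
        ``"log10p1"`` (default) runs the Welch test on log10(x+1)-transformed
        mean normalized counts; ``"linear"`` uses the raw means. Fold change
        is always on the untransformed means.

    Returns
    -------
    EnrichmentResult or NoTestResult
        ``NoTestResult`` when no class-positive deorphaned OR is present in
        the abundance table.
    """
    if class_selector not in _CLASS_SELECTORS:
        raise ValueError(f"class selector must be one of {_CLASS_SELECTORS}, got {class_selector!r}")
    if welch_scale not in ("log10p1", "linear"):
        raise ValueError("welch_scale must be 'log10p1' or 'linear'")
    if "top_decile" not in abundance.columns or "mean_norm" not in abundance.columns:
        raise ValueError("abundance table needs 'mean_norm' and 'top_decile' columns")

    if len(pairs) == 0:
        return NoTestResult(class_selector, "empty ligand-pair table")

    deorphaned = pd.Index(pairs["or_id"].unique()).intersection(abundance.index)
    class_ors = _class_positive(pairs, class_selector).intersection(abundance.index)
    if len(class_ors) == 0:
        return NoTestResult(class_selector, f"no deorphaned OR of class {class_selector!r} in abundance table")

    n = len(class_ors)
    k = int(abundance.loc[class_ors, "top_decile"].sum())
    p = binom_two_tail(k, n, p0)
    low, high = wilson_interval(k, n, confidence)

    result = dict(
        class_selector=class_selector, k=k, n=n, p0=p0,
        p_two_tail=p, wilson_low=low, wilson_high=high,
    )
    comparison = deorphaned.difference(class_ors)
    if len(comparison) > 0:
        a = abundance.loc[class_ors, "mean_norm"].to_numpy(dtype=float)
        b = abundance.loc[comparison, "mean_norm"].to_numpy(dtype=float)
        if b.mean() > 0:
            result["fold_change"] = fold_change(a, b)
        if len(a) >= 2 and len(b) >= 2:
            if welch_scale == "log10p1":
                ta, tb = np.log10(a + 1.0), np.log10(b + 1.0)
            else:
                ta, tb = a, b
            t, df, wp = welch_t(ta, tb)
            result.update(welch_t=t, welch_df=df, welch_p=wp)
    return EnrichmentResult(**result)
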