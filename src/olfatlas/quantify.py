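"""Count normalization and per-species OR abundance summaries.

Bulk RNA-seq of whole olfactory mucosa proxies the abundance of each
olfactory sensory neuron subtype by the summed mRNA of the receptor it
expresses. Raw counts are made comparable across replicates by
median-of-ratios size factors; per-receptor summaries then report the mean
normalized count, its SEM, the percent of total OR expression, an
expressed flag (>= 1.0 normalized counts in at least one replicate), and
membership in the species' top expression decile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "estimate_size_factors",
    "normalize",
    "summarize_abundance",
    "flag_expressed",
    "top_decile_set",
]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, takes the median over genes of
    ``counts[g, s] / geomean_g`` where ``geomean_g`` is the geometric mean of
    gene g across samples. Genes with a zero anywhere (geometric mean 0) are
    excluded from the median; at least one all-positive gene is required.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative genes x samples count matrix.

    Returns
    -------
    pandas.Series
        One positive factor per sample, geometric mean exactly rescaled to 1.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("normalization impossible: no gene has positive counts in every sample")
    logs = np.log(mat[allpos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_ratios = logs - log_geomean
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (zeros preserved)."""
    sf = pd.Series(size_factors).reindex(counts.columns)
    if sf.isna().any():
        raise ValueError("size_factors must provide one factor per sample")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / sf


def flag_expressed(
    norm: pd.DataFrame,
    threshold: float = 1.0,
    min_replicates: int = 1,
) -> pd.Series:
    """True for genes with >= `threshold` normalized counts in >= `min_replicates` samples.

    The comparison is inclusive: a value of exactly 1.0 counts as expressed
    at the default threshold.
    """
    hits = (norm >= threshold).sum(axis=1)
    return (hits >= min_replicates).rename("expressed")


def summarize_abundance(norm: pd.DataFrame, or_ids) -> pd.DataFrame:
    """Per-OR abundance summary over replicates.

    For every OR: the mean normalized count across samples, the SEM
    (standard deviation with n-1 denominator over sqrt(n)), and the percent
    of total OR expression — computed per sample as
    ``100 * value / sum over ORs`` and then averaged across samples, so each
    individual contributes its own percentage. Per sample those percentages
    sum to 100 whenever the sample's OR total is positive.

    Returns a DataFrame indexed by gene id with columns ``mean_norm``,
    ``sem``, ``pct_total_or``, sorted by ``mean_norm`` descending.
    """
    or_ids = pd.Index(or_ids)
    if len(or_ids) == 0:
        return pd.DataFrame(columns=["mean_norm", "sem", "pct_total_or"])
    missing = or_ids.difference(norm.index)
    if len(missing) > 0:
        raise KeyError(f"OR ids absent from matrix: {list(missing)[:5]}")
    sub = norm.loc[or_ids]
    n = sub.shape[1]
    mean = sub.mean(axis=1)
    sem = sub.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=sub.index)
    totals = sub.sum(axis=0)
    # samples with zero OR total contribute 0% rather than NaN
    pct = (100.0 * sub.div(totals.where(totals > 0), axis="columns")).fillna(0.0)
    out = pd.DataFrame(
        {"mean_norm": mean, "sem": sem.fillna(0.0), "pct_total_or": pct.mean(axis=1)}
    )
    return out.sort_values("mean_norm", ascending=False)


def top_decile_set(
    records: pd.DataFrame,
    percentile: float = 90.0,
) -> set[str]:
    """Genes strictly above the empirical percentile of ``mean_norm``.

    The cutoff is the linear-interpolation percentile of the mean_norm
    vector over the full catalog passed in (by default all ORs, intact and
    disrupted alike); membership is strictly-above, so a flat vector yields
    an empty set. A ``top_decile`` boolean column is added to ``records``
    in place.
    """
    if len(records) == 0:
        records["top_decile"] = pd.Series(dtype=bool)
        return set()
    cutoff = float(np.percentile(records["mean_norm"].to_numpy(dtype=float), percentile))
    mask = records["mean_norm"] > cutoff
    records["top_decile"] = mask
    return set(records.index[mask])
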