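"""Sensory-profile comparison and physicochemical odor-space projection.

Odorants detected by the most abundant OSN subtypes of two species can be
compared in two ways: by their *sensory profiles* — the fraction of each
species' odorant set carrying each human odor descriptor category, compared
with Spearman rank correlation — and by their position in physicochemical
*odor space*, a correlation-matrix PCA of molecular descriptors after
uninformative descriptors are filtered out.

Descriptor filtering drops a descriptor when (checked in this order):

c. any value is missing for any odorant;
a. more than 90% of its values are identical (modal frequency > 0.9);
b. its most common value is more than 19x more common than the second
   most common value (count vs count, strict >).

The rule letters follow the order the thresholds are usually quoted in; the
removal log records which rule fired first for each dropped descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cross_species import pca_correlation

__all__ = [
    "default_sensory_vocabulary",
    "build_sensory_profile",
    "spearman_rho",
    "filter_descriptors",
    "project_odor_space",
]


def default_sensory_vocabulary() -> list[str]:
    """Human odor descriptor categories shipped as the default vocabulary."""
    text = resources.files("olfatlas.data").joinpath("sensory_vocabulary.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def build_sensory_profile(
    odorants,
    annotations: dict[str, set[str]] | pd.DataFrame,
    vocabulary: list[str] | None = None,
) -> pd.Series:
    """Per-category fraction of an odorant set carrying each descriptor.

    Multi-label odorants count once for every category they carry; the
    profile is therefore a vector of proportions in [0, 1] that need not
    sum to 1. The category axis is the supplied vocabulary, defaulting to
    the union of categories seen in the annotations (sorted).

    Raises ``KeyError`` naming the first odorant without any annotation.
    """
    if isinstance(annotations, pd.DataFrame):
        ann = {
            str(od): set(grp["descriptor"].astype(str))
            for od, grp in annotations.groupby("odorant_id")
        }
    else:
        ann = {k: set(v) for k, v in annotations.items()}
    odorants = list(odorants)
    for od in odorants:
        if od not in ann or not ann[od]:
            raise KeyError(f"odorant {od!r} has no descriptor annotation")
    if vocabulary is None:
        vocabulary = sorted(set().union(*(ann[od] for od in odorants))) if odorants else []
    counts = pd.Series(0.0, index=pd.Index(vocabulary, name="category"))
    for od in odorants:
        for cat in ann[od]:
            if cat in counts.index:
                counts[cat] += 1.0
    if odorants:
        counts /= len(odorants)
    return counts.rename("frequency")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Mid-ranks are used for ties. Constant input vectors leave the statistic
    undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman rho undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def filter_descriptors(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop uninformative physicochemical descriptors (columns).

    Rules, checked in order for each descriptor: (c) any missing value;
    (a) modal value frequency > 0.9; (b) modal count > 19x the second
    modal count. Returns the reduced matrix and a removal log with columns
    ``descriptor`` and ``rule`` in {"missing", "near_constant",
    "mode_ratio"}. Filtering is idempotent.
    """
    removed = []
    keep = []
    n = len(matrix)
    for col in matrix.columns:
        values = matrix[col]
        if values.isna().any():
            removed.append((col, "missing"))
            continue
        vc = values.value_counts()
        modal = int(vc.iloc[0])
        if n > 0 and modal / n > 0.9:
            removed.append((col, "near_constant"))
            continue
        second = int(vc.iloc[1]) if len(vc) > 1 else 0
        if modal > 19 * second:
            removed.append((col, "mode_ratio"))
            continue
        keep.append(col)
    log = pd.DataFrame(removed, columns=["descriptor", "rule"])
    return matrix[keep], log


@dataclass(frozen=True)
class OdorSpace:
    """PCA projection of odorants with an optional highlighted subset."""

    scores: pd.DataFrame
    variance_explained: np.ndarray
    highlight: pd.Series  # boolean per odorant


def project_odor_space(reduced: pd.DataFrame, highlight=None) -> OdorSpace:
    """Project odorants into PCA odor space fitted on the full set.

    The basis is fitted on *all* rows of the reduced descriptor matrix;
    the ``highlight`` set (e.g. the molecules detected by top-decile
    receptors) is only flagged for plotting, so removing a highlighted
    odorant changes other scores only through the shared basis refit.
    Requires a matrix free of missing values and zero-variance columns
    (run :func:`filter_descriptors` first).
    """
    if reduced.isna().any().any():
        raise ValueError("descriptor matrix contains missing values; filter first")
    res = pca_correlation(reduced)
    mask = pd.Series(False, index=reduced.index, name="highlight")
    if highlight is not None:
        mask[mask.index.isin(set(highlight))] = True
    return OdorSpace(scores=res.scores, variance_explained=res.variance_explained, highlight=mask)
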