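"""Clonal/subclonal decomposition of VAF distributions, mutation-rate
normalization and the cohort comparison tests.

Somatic mutations of a tumour or clone separate into a clonal population
(present in every cell, higher variant allele frequency) and subclonal
populations (later, partial).  The split is found with a two-centre
1-dimensional k-means on the VAFs; the border is the midpoint of the two
converged centres.  Mutation rates are normalized to population
doublings computed from days in culture and the mean doubling time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

__all__ = [
    "ClonalitySplit",
    "RateResult",
    "VafClonality",
    "split_clonal_subclonal",
    "rate_per_doubling",
    "ttest_unpaired",
    "ttest_paired",
    "compare_clonal_subclonal_exposures",
]

MIN_PER_CLASS = 300  # samples with fewer clonal or subclonal mutations are excluded


@dataclass
class ClonalitySplit:
    """Result of a clonal/subclonal VAF split."""

    border_vaf: float
    clonal_count: int
    subclonal_count: int
    included: bool
    labels: np.ndarray  # 1 = clonal (upper cluster), 0 = subclonal

    def __post_init__(self) -> None:
        if not (0 < self.border_vaf < 1):
            raise ValidationError("border VAF must lie strictly inside (0, 1)")


@dataclass
class RateResult:
    """Mutation rate normalized to population doublings."""

    total_mutations: float
    days: float
    doubling_time_hours: float
    population_doublings: float
    rate_per_doubling: float
    rate_per_mb: float


class VafClonality(BaseEstimator, ClusterMixin):
    """Two-centre 1-D k-means separating clonal from subclonal VAFs.

    In one dimension the optimal two-cluster assignment is a split of the
    sorted values, so the estimator minimizes the k-means objective
    exactly by scanning all n-1 sorted split points with prefix sums
    (deterministic, globally optimal; a converged Lloyd iteration is a
    fixed point of this optimum).  Ties between equal-cost splits go to
    the leftmost split.  The clonal/subclonal border is the midpoint of
    the two cluster means; the upper cluster is "clonal".

    Fitted attributes: ``cluster_centers_`` (sorted ascending),
    ``border_``, ``labels_`` (1 = clonal), ``split_`` (a
    :class:`ClonalitySplit` including the >= ``min_per_class`` inclusion
    flag).
    """

    def __init__(self, min_per_class: int = MIN_PER_CLASS):
        self.min_per_class = min_per_class

    def fit(self, X, y=None) -> "VafClonality":
        v = np.asarray(X, dtype=float).ravel()
        if v.ndim != 1 or len(v) < 2:
            raise ValidationError("need at least two VAF values")
        if np.unique(v).size < 2:
            raise ValidationError("all VAFs identical; no two-centre model exists")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("VAFs must lie in [0, 1]")
        s = np.sort(v)
        n = len(s)
        c1 = np.cumsum(s)
        c2 = np.cumsum(s * s)
        i = np.arange(1, n)  # split: s[:i] vs s[i:]
        sse_lo = c2[i - 1] - c1[i - 1] ** 2 / i
        sse_hi = (c2[-1] - c2[i - 1]) - (c1[-1] - c1[i - 1]) ** 2 / (n - i)
        best = int(np.argmin(sse_lo + sse_hi))  # argmin takes the leftmost tie
        k = i[best]
        centers = np.array([c1[k - 1] / k, (c1[-1] - c1[k - 1]) / (n - k)])
        border = float(centers.mean())
        labels = (v >= border).astype(int)
        clonal = int(labels.sum())
        subclonal = len(v) - clonal
        self.cluster_centers_ = np.sort(centers)
        self.border_ = border
        self.labels_ = labels
        self.split_ = ClonalitySplit(
            border_vaf=border,
            clonal_count=clonal,
            subclonal_count=subclonal,
            included=(clonal >= self.min_per_class and subclonal >= self.min_per_class),
            labels=labels,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "border_")
        v = np.asarray(X, dtype=float).ravel()
        return (v >= self.border_).astype(int)


def split_clonal_subclonal(vafs, rng_seed: int = 0) -> ClonalitySplit:
    """Split VAFs into clonal/subclonal by deterministic 1-D 2-means.

    ``rng_seed`` is accepted for interface stability but unused: the
    initialization is deterministic (quantile-based), so the result is a
    pure function of the data.
    """
    return VafClonality().fit(vafs).split_


def rate_per_doubling(
    n_mutations: float, days: float, doubling_time_hours: float, genome_mb: float
) -> RateResult:
    """Mutation rate per population doubling and per megabase.

    doublings = days * 24 / doubling_time_hours; rate = n / doublings.
    """
    if days <= 0 or doubling_time_hours <= 0 or genome_mb <= 0:
        raise ValidationError("days, doubling time and genome size must be positive")
    if n_mutations < 0:
        raise ValidationError("mutation count must be non-negative")
    doublings = days * 24.0 / doubling_time_hours
    rate = n_mutations / doublings
    return RateResult(
        total_mutations=n_mutations,
        days=days,
        doubling_time_hours=doubling_time_hours,
        population_doublings=doublings,
        rate_per_doubling=rate,
        rate_per_mb=rate / genome_mb,
    )


def ttest_unpaired(group_a, group_b, equal_var: bool = True) -> dict:
    """Two-sided unpaired t-test (pooled-variance by default; Welch with
    ``equal_var=False``); reports means, SDs and SEMs."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "sem_a": float(stats.sem(a)),
        "sem_b": float(stats.sem(b)),
        "equal_var": equal_var,
    }


def ttest_paired(values_a, values_b) -> dict:
    """Two-sided paired t-test on aligned measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired inputs must be aligned")
    if len(a) < 2:
        raise ValidationError("need at least two pairs")
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": float((a - b).mean())}


def compare_clonal_subclonal_exposures(
    clonal: pd.DataFrame, subclonal: pd.DataFrame
) -> pd.DataFrame:
    """Paired per-signature comparison of clonal vs subclonal signature
    contributions.

    Inputs are samples x signatures exposure tables from the same
    reference set; rows are matched by sample id, samples missing one
    compartment are excluded.  Exposures are converted to relative
    contributions per sample (summing to 1 within each compartment)
    before the paired two-sided t-test per signature.
    """
    if list(clonal.columns) != list(subclonal.columns):
        raise ValidationError("clonal and subclonal fits must share signatures")
    common = clonal.index.intersection(subclonal.index)
    if len(common) < 2:
        raise ValidationError("need at least two samples with both compartments")
    c = clonal.loc[common]
    s = subclonal.loc[common]
    c_rel = c.div(c.sum(axis=1), axis=0)
    s_rel = s.div(s.sum(axis=1), axis=0)
    rows = []
    for sig in clonal.columns:
        a, b = c_rel[sig].to_numpy(), s_rel[sig].to_numpy()
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append(
            {
                "signature": sig,
                "mean_clonal": float(a.mean()),
                "mean_subclonal": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "n_samples": len(common),
            }
        )
    return pd.DataFrame(rows)
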