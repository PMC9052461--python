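"""Normalization, differential filtering and three-state discretization.

Every profile is normalized gene-wise to zero mean and unit standard
deviation, screened with a per-feature one-way ANOVA across the class
groups (optionally with moderated, shrunken variances), and finally
mapped to three states {-1, 0, +1} with cut points one standard
deviation either side of the mean.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import ClassLabels, DiscretizedMatrix, OmicsMatrix

__all__ = [
    "DifferentialResult",
    "zscore_normalize",
    "drop_constant_features",
    "differential_filter",
    "discretize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature F statistic, p-value and keep decision (p < alpha)."""

    feature_ids: tuple[str, ...]
    statistic: np.ndarray
    p_value: np.ndarray
    kept: np.ndarray
    alpha: float

    @property
    def kept_ids(self) -> tuple[str, ...]:
        return tuple(f for f, k in zip(self.feature_ids, self.kept) if k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": list(self.feature_ids),
            "F": self.statistic,
            "p": self.p_value,
            "kept": self.kept,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def drop_constant_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Remove features with zero variance (z-scoring is undefined for them)."""
    sd = matrix.values.std(axis=1)
    const = sd == 0
    if const.any():
        dropped = [f for f, c in zip(matrix.feature_ids, const) if c]
        log.warning("dropping %d constant feature(s): %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
        keep = [f for f, c in zip(matrix.feature_ids, const) if not c]
        return matrix.subset_features(keep)
    return matrix


def zscore_normalize(matrix: OmicsMatrix, ddof: int = 0) -> OmicsMatrix:
    """Zero-mean, unit-variance normalization of every feature row.

    Uses the population convention (divisor n, ``ddof=0``) by default;
    pass ``ddof=1`` for the sample convention.  Constant features are an
    error — drop them first with :func:`drop_constant_features`.
    """
    mu = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=ddof, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        bad = [f for f, z in zip(matrix.feature_ids, zero) if z]
        raise ValueError(f"constant feature(s) cannot be z-scored: {bad[:10]}")
    return OmicsMatrix(matrix.feature_ids, matrix.sample_ids,
                       (matrix.values - mu) / sd)


def differential_filter(matrix: OmicsMatrix, labels: ClassLabels,
                        alpha: float = 0.05,
                        prior_df: float = 0.0) -> DifferentialResult:
    """Per-feature one-way ANOVA across class groups; keep p < alpha.

    With ``prior_df`` > 0 a moderated variant is used: the per-feature
    within-group variance is shrunk toward the grand mean of those
    variances with prior weight ``prior_df`` (in pseudo-degrees of
    freedom), and the residual degrees of freedom grow accordingly.
    This emulates empirical-Bayes variance moderation without fitting a
    prior.  No multiple-testing correction is applied.
    """
    if list(matrix.sample_ids) != list(labels.sample_ids):
        raise ValueError("matrix and labels must be aligned on samples")
    y = labels.codes()
    n_classes = labels.n_classes
    counts = np.bincount(y, minlength=n_classes)
    small = [labels.class_names[c] for c in range(n_classes) if counts[c] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")

    X = matrix.values
    n = X.shape[1]
    grand = X.mean(axis=1, keepdims=True)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for c in range(n_classes):
        grp = X[:, y == c]
        m = grp.mean(axis=1, keepdims=True)
        ss_between += counts[c] * (m[:, 0] - grand[:, 0]) ** 2
        ss_within += ((grp - m) ** 2).sum(axis=1)

    df_b = n_classes - 1
    df_w = n - n_classes
    ms_between = ss_between / df_b
    s2 = ss_within / df_w
    if prior_df > 0:
        s2_0 = s2.mean()
        s2_post = (prior_df * s2_0 + df_w * s2) / (prior_df + df_w)
        df_post = df_w + prior_df
    else:
        s2_post, df_post = s2, df_w

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_between / s2_post
    # zero within-class variance with distinct means: infinitely significant
    F = np.where((s2_post == 0) & (ms_between > 0), np.inf, F)
    F = np.where((s2_post == 0) & (ms_between == 0), 0.0, F)
    p = scipy.stats.f.sf(F, df_b, df_post)
    kept = p < alpha
    return DifferentialResult(matrix.feature_ids, F, p, kept, alpha)


def discretize(matrix: OmicsMatrix) -> DiscretizedMatrix:
    """Map each feature to three states with cut points at mean +/- sigma.

    value < mu - sigma -> -1; value > mu + sigma -> +1; otherwise 0
    (boundary values map to 0 by the strict inequalities).  On z-scored
    input the cut points are simply -1 and +1.  The per-feature mean and
    standard deviation are recomputed here so the rule is total on any
    finite matrix.
    """
    mu = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, keepdims=True)
    lo = mu - sd
    hi = mu + sd
    states = np.zeros(matrix.values.shape, dtype=np.int8)
    states[matrix.values < lo] = -1
    states[matrix.values > hi] = 1
    return DiscretizedMatrix(matrix.feature_ids, matrix.sample_ids, states)
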