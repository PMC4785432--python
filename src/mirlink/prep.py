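"""Expression-matrix preprocessing: quantile normalization and the detection filter.

Matrices are pandas DataFrames with features in rows and samples in columns,
on a log2-intensity scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DetectionRule", "quantile_normalize", "detection_filter", "median_collapse"]


@dataclass(frozen=True)
class DetectionRule:
    """Thresholds for calling a feature detected above array background.

    A feature is detected when its intensity exceeds
    ``negctrl_mean + sd_multiplier * negctrl_sd`` (strictly) in at least
    ``min_sample_fraction`` of the samples.
    """

    min_sample_fraction: float = 1.0 / 3.0
    sd_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_sample_fraction <= 1.0):
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one empirical distribution.

    The reference distribution is the across-column mean of the order
    statistics.  Ties within a column receive the mean of the reference values
    at their tied ranks, so the operation is idempotent and rank-preserving.

    A single-column matrix is returned unchanged with a warning (there is
    nothing to equalize).
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix (no NaN)")
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize on a single-sample matrix is the identity")
        return matrix.copy()

    values = matrix.to_numpy(dtype=float)
    n_rows = values.shape[0]
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        # assign each tied run the mean of the reference over its rank span
        assigned = np.empty(n_rows)
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    matrix: pd.DataFrame,
    negctrl_mean: float,
    negctrl_sd: float,
    rule: DetectionRule = DetectionRule(),
) -> set[str]:
    """Return ids of features expressed above the negative-control background.

    Detection requires intensity strictly above
    ``negctrl_mean + rule.sd_multiplier * negctrl_sd`` in a fraction of
    samples of at least ``rule.min_sample_fraction``.
    """
    if negctrl_sd < 0:
        raise ValueError("negctrl_sd must be >= 0")
    if matrix.size == 0:
        return set()
    threshold = negctrl_mean + rule.sd_multiplier * negctrl_sd
    frac_above = (matrix.to_numpy(dtype=float) > threshold).mean(axis=1)
    keep = frac_above >= rule.min_sample_fraction
    return set(matrix.index[keep])


def median_collapse(matrix: pd.DataFrame, probe_to_feature: pd.Series) -> pd.DataFrame:
    """Collapse replicated probes to one row per feature by the median intensity."""
    mapped = matrix.copy()
    mapped.index = probe_to_feature.reindex(matrix.index)
    return mapped.groupby(level=0).median()
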