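"""Differential expression between timepoints with an empirical-Bayes moderated t-test.

The model follows the standard microarray linear-model/shrinkage approach:
per-feature least squares for the timepoint effect (within-subject differences
in paired mode), residual variances shrunk toward a common prior by
moment-matching a scaled inverse-chi-square (equivalently, a scaled F
distribution for the observed variances), and moderated t statistics referred
to a Student t with augmented degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModerationParams",
    "fit_moderated",
    "estimate_moderation",
    "adjust_pvalues",
    "pca_group_test",
]


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom and prior variance for variance shrinkage.

    ``d0 = 0`` disables shrinkage (ordinary t); ``d0 = inf`` collapses every
    residual variance to ``s0_sq``.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y for large y, ~ 1/y^2 for small y
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match a scaled-F / inverse-chi-square prior to observed variances.

    Works on ``log(s2)`` whose mean and variance identify the prior degrees of
    freedom ``d0`` and prior variance ``s0_sq`` through digamma/trigamma
    relations.  Features with zero residual variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        warnings.warn("all residual variances are zero; moderation degenerates to d0=inf")
        return ModerationParams(d0=np.inf, s0_sq=1e-12)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def _paired_differences(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    by_subject = samples.groupby("subject")
    diffs = {}
    for subject, grp in by_subject:
        tps = set(grp["timepoint"])
        if tps != {"T0", "T1"}:
            raise ValueError(f"paired mode requires T0 and T1 for subject {subject!r}")
        s0 = grp.loc[grp["timepoint"] == "T0", "sample_id"].iloc[0]
        s1 = grp.loc[grp["timepoint"] == "T1", "sample_id"].iloc[0]
        diffs[subject] = matrix[s1] - matrix[s0]
    return pd.DataFrame(diffs)


def fit_moderated(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    paired: bool = True,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    moderation: ModerationParams | None = None,
) -> pd.DataFrame:
    """Test each feature for a T1 - T0 expression shift with variance moderation.

    Parameters
    ----------
    matrix
        features x samples log2 intensities; columns must appear in
        ``samples['sample_id']``.
    samples
        sample sheet with columns ``sample_id``, ``subject``, ``timepoint``.
    paired
        if True (default), fit on within-subject T1 - T0 differences; if
        False, fit the two-group timepoint contrast ignoring pairing.
    moderation
        optional fixed prior; estimated from the data when None.

    Returns
    -------
    DataFrame indexed by feature with columns ``effect`` (log2 fold change
    T1 - T0), ``t`` (moderated t), ``p``, ``p_adj`` and ``is_de``.
    """
    samples = samples.set_index("sample_id", drop=False).loc[list(matrix.columns)]
    tps = set(samples["timepoint"])
    if not {"T0", "T1"} <= tps:
        raise ValueError("both timepoints T0 and T1 must be present")

    if paired:
        diffs = _paired_differences(matrix, samples)
        n = diffs.shape[1]
        if n < 2:
            raise ValueError("paired fit needs at least 2 subjects")
        effect = diffs.mean(axis=1).to_numpy()
        resid_df = n - 1
        s2 = diffs.var(axis=1, ddof=1).to_numpy()
        stdev_unscaled = 1.0 / np.sqrt(n)
    else:
        g0 = matrix.loc[:, samples.index[samples["timepoint"] == "T0"]]
        g1 = matrix.loc[:, samples.index[samples["timepoint"] == "T1"]]
        n0, n1 = g0.shape[1], g1.shape[1]
        if min(n0, n1) < 2:
            raise ValueError("unpaired fit needs at least 2 samples per timepoint")
        effect = (g1.mean(axis=1) - g0.mean(axis=1)).to_numpy()
        resid_df = n0 + n1 - 2
        ss = g0.sub(g0.mean(axis=1), axis=0).pow(2).sum(axis=1) + g1.sub(
            g1.mean(axis=1), axis=0
        ).pow(2).sum(axis=1)
        s2 = (ss / resid_df).to_numpy()
        stdev_unscaled = np.sqrt(1.0 / n0 + 1.0 / n1)

    if moderation is None:
        moderation = estimate_moderation(s2, resid_df)
    d0, s0_sq = moderation.d0, moderation.s0_sq

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
        df_total = d0 + resid_df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (stdev_unscaled * np.sqrt(post_var))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = adjust_pvalues(p, adjust)
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "is_de": p_adj < alpha,
        },
        index=matrix.index,
    )


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``benjamini_hochberg``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh", "bh": "fdr_bh"}
    if method not in key:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key[method])[1]


def pca_group_test(
    matrix: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo permutation test of group separation in PCA sample space.

    The statistic is the between-group fraction of the total inertia of the
    sample scores (equivalently, of the column-centered data, since the full
    PC rotation preserves distances).  The p-value uses the add-one
    convention, so the smallest attainable value at ``n_perm`` replicates is
    ``1 / (n_perm + 1)``.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != matrix.shape[1]:
        raise ValueError("one group label per sample is required")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")

    # samples x features, feature-centered: inertia of PCA scores
    x = matrix.to_numpy(dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    total_ss = float((x**2).sum())
    if total_ss == 0.0:
        return 0.0, 1.0

    def between_frac(lab: np.ndarray) -> float:
        bss = 0.0
        for g in labels:
            sub = x[lab == g]
            bss += sub.shape[0] * float((sub.mean(axis=0) ** 2).sum())
        return bss / total_ss

    observed = between_frac(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if between_frac(rng.permutation(groups)) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p
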