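"""Per-miRNA target enrichment among anticorrelated differentially expressed genes.

Two complementary tests identify miRNAs whose validated targets respond to the
condition: a hypergeometric test on the overlap between a miRNA's targetome
and its anticorrelated DE genes, and a rank-based generalization (one-sided
Wilcoxon rank-sum on DE p-values) that avoids fixing a significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_pvalues

__all__ = [
    "TargetDB",
    "correlate_pairs",
    "anticorrelated_set",
    "hypergeom_enrichment",
    "rank_enrichment",
    "select_enriched",
    "correlate_covariates",
]


@dataclass
class TargetDB:
    """Map from miRNA id to its set of experimentally validated target genes."""

    targets: dict[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        self.targets = {m: frozenset(g) for m, g in self.targets.items()}

    def tested_mirnas(self) -> list[str]:
        """miRNAs with a non-empty targetome (the only ones that can be tested)."""
        return [m for m, g in self.targets.items() if g]

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.targets.get(mirna, frozenset())

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets


def correlate_pairs(
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    mirna_ids,
    gene_ids,
) -> pd.DataFrame:
    """Pearson correlation and two-sided t-based p for every (miRNA, gene) pair.

    Both matrices must share identical sample columns (>= 3 samples).
    Zero-variance features yield r = 0 with ``degenerate = True``.
    """
    if list(mirna_matrix.columns) != list(gene_matrix.columns):
        raise ValueError("matrices must share identical sample columns")
    n = mirna_matrix.shape[1]
    if n < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    mirna_ids = list(mirna_ids)
    gene_ids = list(gene_ids)

    x = mirna_matrix.loc[mirna_ids].to_numpy(dtype=float)
    y = gene_matrix.loc[gene_ids].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    degenerate = np.add.outer(xs == 0, ys == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)

    mi, gi = np.meshgrid(np.arange(len(mirna_ids)), np.arange(len(gene_ids)), indexing="ij")
    return pd.DataFrame(
        {
            "mirna": np.asarray(mirna_ids, dtype=object)[mi.ravel()],
            "gene": np.asarray(gene_ids, dtype=object)[gi.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
            "degenerate": degenerate.ravel(),
        }
    )


def anticorrelated_set(
    table: pd.DataFrame,
    mirna: str,
    deg_ids,
    r_max: float = -0.5,
    p_max: float = 0.05,
) -> set[str]:
    """DE genes strictly below the anticorrelation thresholds for one miRNA."""
    if not r_max < 0:
        raise ValueError("r_max must be negative (anticorrelation threshold)")
    deg_ids = set(deg_ids)
    sub = table[(table["mirna"] == mirna) & (table["r"] < r_max) & (table["p"] < p_max)]
    return set(sub["gene"]) & deg_ids


def hypergeom_enrichment(
    targets: frozenset | set,
    anticorr: frozenset | set,
    universe_size: int,
) -> float | None:
    """Upper-tail hypergeometric p for target over-representation.

    Population ``N = universe_size``, successes ``K = |targets|``, draws
    ``n = |anticorr|``, observed ``k = |targets & anticorr|``; returns
    ``P(X >= k)``.  miRNAs without targets are skipped (``None``), not given
    p = 1, so they never dilute the multiple-testing correction.
    """
    targets = set(targets)
    if not targets:
        return None
    anticorr = set(anticorr)
    if universe_size < len(targets | anticorr):
        raise ValueError("universe smaller than the union of targets and anticorrelated genes")
    k = len(targets & anticorr)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(targets), len(anticorr)))


def rank_enrichment(
    targets: frozenset | set,
    de_pvalues: pd.Series | dict,
    exact_max: int = 10,
) -> float | None:
    """One-sided rank-sum test: are targets' DE p-values stochastically smaller?

    Compares the DE p-values of the miRNA's targets against all other genes in
    the universe.  Exact enumeration is used when the smaller group has at
    most ``exact_max`` members and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    de_pvalues = pd.Series(de_pvalues)
    targets = set(targets) & set(de_pvalues.index)
    if not targets:
        return None
    others = [g for g in de_pvalues.index if g not in targets]
    if not others:
        raise ValueError("targets cover the whole universe; no comparison group")
    x = de_pvalues.loc[list(targets)].to_numpy(dtype=float)
    y = de_pvalues.loc[others].to_numpy(dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= exact_max and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="less", method=method, use_continuity=True)
    return float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Per-miRNA enrichment decision table."""

    table: pd.DataFrame
    enriched_mirnas: list[str] = field(default_factory=list)
    anticorr_union: set[str] = field(default_factory=set)


def select_enriched(
    hyper: dict[str, float],
    rank: dict[str, float],
    corr: pd.DataFrame,
    deg_ids,
    targetdb: TargetDB,
    q: float = 0.10,
    r_max: float = -0.5,
    p_max: float = 0.05,
) -> EnrichmentResult:
    """Combine both tests into the final enriched-miRNA call.

    Each test family is BH-adjusted separately over the tested miRNAs.  A
    miRNA is enriched when either FDR falls below ``q`` AND at least one of
    its targets is anticorrelated (r < ``r_max``, p < ``p_max``) among the DE
    genes — significance by rank alone with no anticorrelated target does not
    qualify.
    """
    mirnas = sorted(set(hyper) | set(rank))
    fdr_h = _bh_map(hyper, mirnas)
    fdr_r = _bh_map(rank, mirnas)

    rows = []
    enriched_list: list[str] = []
    union: set[str] = set()
    for m in mirnas:
        anticorr = anticorrelated_set(corr, m, deg_ids, r_max=r_max, p_max=p_max)
        anticorr &= set(targetdb[m])
        significant = (fdr_h.get(m, np.nan) < q) or (fdr_r.get(m, np.nan) < q)
        enriched = bool(significant and len(anticorr) >= 1)
        if enriched:
            enriched_list.append(m)
            union |= anticorr
        rows.append(
            {
                "mirna": m,
                "n_targets": len(targetdb[m]),
                "n_anticorr_targets": len(anticorr),
                "p_hyper": hyper.get(m, np.nan),
                "p_rank": rank.get(m, np.nan),
                "fdr_hyper": fdr_h.get(m, np.nan),
                "fdr_rank": fdr_r.get(m, np.nan),
                "anticorr_target_ids": ";".join(sorted(anticorr)),
                "enriched": enriched,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna", drop=False)
    return EnrichmentResult(table=table, enriched_mirnas=enriched_list, anticorr_union=union)


def _bh_map(pmap: dict[str, float], mirnas: list[str]) -> dict[str, float]:
    keys = [m for m in mirnas if m in pmap and pmap[m] is not None and np.isfinite(pmap[m])]
    if not keys:
        return {}
    adj = adjust_pvalues([pmap[m] for m in keys], "benjamini_hochberg")
    return dict(zip(keys, adj))


def correlate_covariates(
    mirna_deltas: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson and Spearman correlation of per-subject miRNA changes vs covariates.

    ``mirna_deltas``: miRNAs x subjects (T1 - T0 change); ``covariates``:
    subjects x variables.  Constant inputs are flagged degenerate with r = 0.
    """
    shared = [s for s in mirna_deltas.columns if s in covariates.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared subjects")
    rows = []
    for m in mirna_deltas.index:
        d = mirna_deltas.loc[m, shared].to_numpy(dtype=float)
        for var in covariates.columns:
            c = covariates.loc[shared, var].to_numpy(dtype=float)
            degenerate = np.std(d) == 0 or np.std(c) == 0
            if degenerate:
                pr, pp, sr, sp = 0.0, 1.0, 0.0, 1.0
            else:
                pr, pp = stats.pearsonr(d, c)
                sr, sp = stats.spearmanr(d, c)
            rows.append(
                {
                    "mirna": m,
                    "variable": var,
                    "pearson_r": float(pr),
                    "pearson_p": float(pp),
                    "spearman_rho": float(sr),
                    "spearman_p": float(sp),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
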