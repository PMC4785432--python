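"""End-to-end orchestration: prep -> differential expression -> enrichment ->
GGM validation -> network summaries, with a manifest for reproducibility.

The pipeline can run fully in memory (`run_study`) or against files
(`run_pipeline`), writing every intermediate as TSV so stages can be rerun
individually from saved outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .diffexpr import fit_moderated, pca_group_test
from .enrichment import (
    TargetDB,
    correlate_pairs,
    hypergeom_enrichment,
    rank_enrichment,
    select_enriched,
)
from .ggm import validate_mirnas
from .netutils import first_neighbor_subnetwork, fit_power_law, topology_summary
from .prep import DetectionRule, detection_filter, quantile_normalize
from .simulate import ExpressionStudy

__all__ = ["PipelineParams", "PipelineConfig", "run_study", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the workflow, with the study's defaults."""

    gene_alpha: float = 0.05  # Bonferroni threshold for genes
    mirna_alpha: float = 0.05  # BH threshold for miRNAs
    r_max: float = -0.5
    p_max: float = 0.05
    enrichment_fdr: float = 0.10
    rho: float = 0.03
    n_rep: int = 500
    n_perm: int = 999
    paired: bool = True
    normalize: bool = True
    filter_before_normalize: bool = False
    detection: DetectionRule = field(default_factory=DetectionRule)

    def __post_init__(self) -> None:
        if not self.r_max < 0:
            raise ValueError("r_max must be negative (anticorrelation threshold)")
        for name in ("gene_alpha", "mirna_alpha", "p_max", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.n_rep < 1 or self.n_perm < 1:
            raise ValueError("n_rep and n_perm must be >= 1")


@dataclass
class PipelineConfig:
    """File-based configuration: input paths plus parameters and the master seed."""

    gene_matrix: str
    mirna_matrix: str
    sample_sheet: str
    targetdb_gmt: str
    ppi_sif: str
    out_dir: str
    negctrl_mean: float = 6.0
    negctrl_sd: float = 0.5
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0


def run_study(
    study: ExpressionStudy,
    targetdb: TargetDB,
    ppi,
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
) -> dict:
    """Run the whole analysis in memory and return every stage's result.

    Stages: quantile normalization and the miRNA detection filter; paired
    moderated DE on the experimental cohort (genes Bonferroni, miRNAs BH) plus
    the PCA permutation test; per-miRNA target-enrichment tests with
    anticorrelation filtering; GGM permutation validation on each validation
    timepoint; first-neighbour network topology around the anticorrelated
    target union.
    """
    ss = np.random.SeedSequence(seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(["pca", "ggm_t0", "ggm_t1"], ss.spawn(3))}

    genes = study.gene_matrix
    mirnas = study.mirna_matrix
    if params.filter_before_normalize:
        detected = detection_filter(
            mirnas[study.cohort_samples("experimental")],
            study.negctrl_mean, study.negctrl_sd, params.detection,
        )
        mirnas = mirnas.loc[sorted(detected)]
    if params.normalize:
        genes = quantile_normalize(genes)
        mirnas = quantile_normalize(mirnas)
    if not params.filter_before_normalize:
        detected = detection_filter(
            mirnas[study.cohort_samples("experimental")],
            study.negctrl_mean, study.negctrl_sd, params.detection,
        )
        mirnas = mirnas.loc[sorted(detected)]

    exp_samples = study.cohort_samples("experimental")
    sheet_exp = study.samples[study.samples["cohort"] == "experimental"]
    gene_de = fit_moderated(
        genes[exp_samples], sheet_exp, paired=params.paired,
        alpha=params.gene_alpha, adjust="bonferroni",
    )
    mirna_de = fit_moderated(
        mirnas[exp_samples], sheet_exp, paired=params.paired,
        alpha=params.mirna_alpha, adjust="benjamini_hochberg",
    )
    pca_stat, pca_p = pca_group_test(
        mirnas[exp_samples],
        sheet_exp.set_index("sample_id").loc[exp_samples, "timepoint"].to_numpy(),
        n_perm=params.n_perm,
        seed=seeds["pca"],
    )

    deg_ids = list(gene_de.index[gene_de["is_de"]])
    demirna_ids = list(mirna_de.index[mirna_de["is_de"]])
    tested = [m for m in demirna_ids if m in targetdb and targetdb[m]]

    universe = list(genes.index)
    universe_size = len(universe)
    de_pvalues = gene_de["p"]

    if tested and deg_ids:
        corr = correlate_pairs(mirnas[exp_samples], genes[exp_samples], tested, deg_ids)
    else:
        corr = pd.DataFrame(columns=["mirna", "gene", "r", "p", "degenerate"])
    hyper, rank = {}, {}
    for m in tested:
        anticorr = set(
            corr[(corr["mirna"] == m) & (corr["r"] < params.r_max) & (corr["p"] < params.p_max)]["gene"]
        )
        hyper[m] = hypergeom_enrichment(targetdb[m] & set(universe), anticorr, universe_size)
        rank[m] = rank_enrichment(targetdb[m], de_pvalues)
    enrich = select_enriched(
        {k: v for k, v in hyper.items() if v is not None},
        {k: v for k, v in rank.items() if v is not None},
        corr, deg_ids, targetdb,
        q=params.enrichment_fdr, r_max=params.r_max, p_max=params.p_max,
    )

    candidate_sets = {
        m: sorted(
            set(enrich.table.loc[m, "anticorr_target_ids"].split(";"))
            - {""}
        )
        for m in enrich.enriched_mirnas
    }
    validation = {}
    for tp, skey in (("T0", "ggm_t0"), ("T1", "ggm_t1")):
        cols = study.cohort_samples("validation", tp)
        if len(cols) >= 5 and candidate_sets:
            validation[tp] = validate_mirnas(
                genes[cols].T, mirnas[cols].T, candidate_sets,
                targetdb, ppi, rho=params.rho, n_rep=params.n_rep, seed=seeds[skey],
            )
        else:
            validation[tp] = pd.DataFrame(
                columns=["mirna", "mse", "r2", "p_mse", "p_r2", "n_rep", "fdr_mse", "fdr_r2"]
            )

    subnet = first_neighbor_subnetwork(ppi, enrich.anticorr_union)
    topology = topology_summary(subnet) if subnet.number_of_nodes() else None
    power_law = None
    if topology is not None:
        positive = [(k, c) for k, c in topology["degree_distribution"].items() if k > 0 and c > 0]
        if len(positive) >= 2:
            power_law = fit_power_law(topology["degree_distribution"])

    return {
        "normalized_genes": genes,
        "normalized_mirnas": mirnas,
        "detected_mirnas": sorted(detected),
        "gene_de": gene_de,
        "mirna_de": mirna_de,
        "pca": {"statistic": pca_stat, "p": pca_p},
        "deg_ids": deg_ids,
        "demirna_ids": demirna_ids,
        "correlations": corr,
        "enrichment": enrich,
        "validation": validation,
        "subnetwork": subnet,
        "topology": topology,
        "power_law": power_law,
        "seeds": seeds,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based end-to-end run; returns the run directory.

    Reads the matrices, sample sheet, GMT targetome and SIF network named in
    the config, executes `run_study`, writes every intermediate as TSV/SIF and
    a flat key-value manifest recording thresholds, seeds and input checksums.
    Re-running with the same config reproduces byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = mio.read_matrix(config.gene_matrix)
    mirnas = mio.read_matrix(config.mirna_matrix)
    sheet = mio.read_sample_sheet(config.sample_sheet)
    _validate_schema(genes, mirnas, sheet)
    targetdb = mio.read_gmt(config.targetdb_gmt, background_size=genes.shape[0])
    ppi = mio.read_sif(config.ppi_sif)

    study = ExpressionStudy(
        gene_matrix=genes, mirna_matrix=mirnas, samples=sheet,
        negctrl_mean=config.negctrl_mean, negctrl_sd=config.negctrl_sd,
    )
    res = run_study(study, targetdb, ppi, config.params, seed=config.seed)

    mio.write_matrix(res["normalized_genes"], out / "genes.normalized.tsv")
    mio.write_matrix(res["normalized_mirnas"], out / "mirnas.normalized.tsv")
    (out / "mirnas.detected.txt").write_text("\n".join(res["detected_mirnas"]) + "\n")
    res["gene_de"].to_csv(out / "gene_de.tsv", sep="\t")
    res["mirna_de"].to_csv(out / "mirna_de.tsv", sep="\t")
    res["correlations"].to_csv(out / "correlations.tsv", sep="\t", index=False)
    res["enrichment"].table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for tp, table in res["validation"].items():
        table.to_csv(out / f"ggm_validation_{tp}.tsv", sep="\t", index=False)
    mio.write_sif(res["subnetwork"], out / "subnetwork.sif")
    if res["topology"] is not None:
        topo = {k: v for k, v in res["topology"].items() if k != "degree_distribution"}
        if res["power_law"] is not None:
            topo.update(
                power_law_beta=res["power_law"].beta,
                power_law_a=res["power_law"].a,
                power_law_r2=res["power_law"].r_squared,
            )
        pd.Series(topo).to_csv(out / "topology.tsv", sep="\t", header=False)

    manifest = {
        "seed": config.seed,
        **{f"param.{k}": v for k, v in asdict(config.params).items()},
        **{f"stage_seed.{k}": v for k, v in res["seeds"].items()},
        "input.gene_matrix.sha256": _sha256(config.gene_matrix),
        "input.mirna_matrix.sha256": _sha256(config.mirna_matrix),
        "input.sample_sheet.sha256": _sha256(config.sample_sheet),
        "input.targetdb.sha256": _sha256(config.targetdb_gmt),
        "input.ppi.sha256": _sha256(config.ppi_sif),
        "pca.statistic": res["pca"]["statistic"],
        "pca.p": res["pca"]["p"],
        "n_degs": len(res["deg_ids"]),
        "n_demirnas": len(res["demirna_ids"]),
        "n_enriched": len(res["enrichment"].enriched_mirnas),
        "n_anticorr_targets": len(res["enrichment"].anticorr_union),
    }
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={json.dumps(v) if isinstance(v, dict) else v}\n")
    return out


def _validate_schema(genes: pd.DataFrame, mirnas: pd.DataFrame, sheet: pd.DataFrame) -> None:
    gcols, mcols = list(genes.columns), list(mirnas.columns)
    if set(gcols) != set(mcols):
        raise ValueError("gene and miRNA matrices must share the same sample columns")
    if set(gcols) != set(sheet["sample_id"]):
        raise ValueError("matrix columns must match the sample sheet")
    exp = sheet[sheet["cohort"] == "experimental"]
    counts = exp.groupby("subject").size()
    if len(counts) and not (counts == 2).all():
        raise ValueError("experimental subjects must appear exactly twice (T0 and T1)")
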