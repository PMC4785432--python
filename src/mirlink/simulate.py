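"""Synthetic paired miRNA/mRNA expression studies with planted regulatory structure.

Emulates a two-timepoint (pre/post) design: an experimental cohort of paired
subjects sampled at both T0 and T1, plus an independent validation cohort
sampled at one timepoint each.  Differential expression is planted as an
additive log2 shift at T1; planted regulator miRNAs are over-expressed at T1
and transmit a negative (repressive) signal to their target genes so that
regulator-target pairs are anticorrelated across samples.  Ground truth is
returned alongside the data for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .discovery import MappedRead, revcomp
from .enrichment import TargetDB

__all__ = [
    "StudyConfig",
    "SyntheticTruth",
    "ExpressionStudy",
    "PlantedLocus",
    "generate_study",
    "generate_target_db",
    "generate_ppi",
    "make_planted_loci",
    "generate_read_set",
]


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic paired pre/post expression study.

    Cohort sizes default to the emulated design: 14 paired experimental
    subjects plus an independent validation cohort of 16 pre-only and 31
    post-only subjects.  All expression is on the log2-intensity scale.
    """

    n_genes: int = 1000
    n_mirnas: int = 60
    n_pairs_experimental: int = 14
    n_t0_validation: int = 16
    n_t1_validation: int = 31
    frac_de_genes: float = 0.10
    frac_de_mirnas: float = 0.20
    de_effect_size: float = 1.5
    n_planted_regulators: int = 5
    targets_per_regulator: int = 8
    repression_strength: float = -1.0
    noise_sd: float = 0.5
    subject_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    negctrl_mean: float = 6.0
    negctrl_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_mirnas", "n_pairs_experimental", "n_t0_validation",
            "n_t1_validation", "n_planted_regulators", "targets_per_regulator",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_de_genes", "frac_de_mirnas"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.repression_strength > 0:
            raise ValueError("repression_strength must be <= 0")
        if self.n_planted_regulators * self.targets_per_regulator > self.n_genes:
            raise ValueError("more planted targets requested than genes available")


@dataclass(frozen=True)
class PlantedLocus:
    """A planted hairpin locus: the precursor interval and its mature arm."""

    contig: str
    start: int
    end: int
    strand: str
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.mature_start < self.mature_end <= self.end):
            raise ValueError("mature interval must lie inside the locus")


@dataclass
class SyntheticTruth:
    de_gene_ids: set[str]
    de_mirna_ids: set[str]
    regulator_ids: set[str]
    regulator_targets: dict[str, set[str]]
    planted_loci: list[PlantedLocus] = field(default_factory=list)


@dataclass
class ExpressionStudy:
    """Paired gene/miRNA matrices with the shared sample sheet.

    ``samples`` columns: sample_id, subject, timepoint (T0/T1), cohort
    (experimental/validation).  Both matrices share the same sample columns.
    """

    gene_matrix: pd.DataFrame
    mirna_matrix: pd.DataFrame
    samples: pd.DataFrame
    negctrl_mean: float
    negctrl_sd: float

    def cohort_samples(self, cohort: str, timepoint: str | None = None) -> list[str]:
        sel = self.samples["cohort"] == cohort
        if timepoint is not None:
            sel &= self.samples["timepoint"] == timepoint
        return list(self.samples.loc[sel, "sample_id"])


def _sample_sheet(config: StudyConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_pairs_experimental):
        subj = f"exp{i + 1:02d}"
        rows.append((f"{subj}_T0", subj, "T0", "experimental"))
        rows.append((f"{subj}_T1", subj, "T1", "experimental"))
    for i in range(config.n_t0_validation):
        subj = f"val{i + 1:02d}"
        rows.append((f"{subj}_T0", subj, "T0", "validation"))
    for i in range(config.n_t1_validation):
        subj = f"val{config.n_t0_validation + i + 1:02d}"
        rows.append((f"{subj}_T1", subj, "T1", "validation"))
    return pd.DataFrame(rows, columns=["sample_id", "subject", "timepoint", "cohort"])


def generate_study(config: StudyConfig) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Simulate the full two-cohort study and return it with its ground truth.

    Per feature, baseline means are drawn from Normal(baseline_mean,
    baseline_sd); a per-subject random intercept correlates the two samples of
    a paired subject; DE features receive ``de_effect_size`` at T1 with a
    random sign; planted regulator miRNAs are forced over-expressed at T1 and
    each target gene receives ``repression_strength`` times the regulator's
    deviation from its baseline, producing negative regulator-target
    correlation.  Planted regulator baselines are kept above the detection
    threshold so the truth is not erased by the detection filter; targets are
    drawn disjointly from the non-DE genes.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    sheet = _sample_sheet(config)
    n_samples = len(sheet)
    is_t1 = (sheet["timepoint"] == "T1").to_numpy()

    n_de_genes = int(round(config.frac_de_genes * config.n_genes))
    n_de_mirnas = int(round(config.frac_de_mirnas * config.n_mirnas))
    if config.n_planted_regulators > config.n_mirnas:
        raise ValueError("more regulators than miRNAs")
    n_de_mirnas = max(n_de_mirnas, config.n_planted_regulators)

    de_mirna_idx = rng.choice(config.n_mirnas, size=n_de_mirnas, replace=False)
    regulator_idx = de_mirna_idx[: config.n_planted_regulators]
    de_gene_idx = rng.choice(config.n_genes, size=n_de_genes, replace=False)

    # targets drawn disjointly from genes without their own planted DE effect
    non_de_genes = np.setdiff1d(np.arange(config.n_genes), de_gene_idx)
    needed = config.n_planted_regulators * config.targets_per_regulator
    if needed > non_de_genes.size:
        raise ValueError("not enough non-DE genes to host the planted targets")
    target_pool = rng.choice(non_de_genes, size=needed, replace=False)
    regulator_targets = {
        mirnas[r]: {
            genes[g]
            for g in target_pool[
                k * config.targets_per_regulator : (k + 1) * config.targets_per_regulator
            ]
        }
        for k, r in enumerate(regulator_idx)
    }

    subj_codes, _ = pd.factorize(sheet["subject"])
    u = rng.normal(0.0, config.subject_sd, size=subj_codes.max() + 1)
    subject_effect = u[subj_codes]

    mirna_mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_mirnas)
    det_threshold = config.negctrl_mean + 1.5 * config.negctrl_sd
    mirna_mu[regulator_idx] = det_threshold + 1.5 + np.abs(
        rng.normal(0.0, 1.0, size=regulator_idx.size)
    )
    mirna_sign = rng.choice([-1.0, 1.0], size=config.n_mirnas)
    mirna_sign[regulator_idx] = 1.0  # regulators over-expressed post
    mirna_de = np.zeros(config.n_mirnas)
    mirna_de[de_mirna_idx] = config.de_effect_size
    mirna_noise = rng.normal(0.0, config.noise_sd, size=(config.n_mirnas, n_samples))
    mirna_vals = (
        mirna_mu[:, None]
        + subject_effect[None, :]
        + (mirna_sign * mirna_de)[:, None] * is_t1[None, :]
        + mirna_noise
    )

    gene_mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    gene_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    gene_de = np.zeros(config.n_genes)
    gene_de[de_gene_idx] = config.de_effect_size
    gene_noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    gene_vals = (
        gene_mu[:, None]
        + subject_effect[None, :]
        + (gene_sign * gene_de)[:, None] * is_t1[None, :]
        + gene_noise
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, r in enumerate(regulator_idx):
        deviation = mirna_vals[r] - mirna_mu[r]  # carries effect + subject + noise
        for g in regulator_targets[mirnas[r]]:
            gene_vals[gene_index[g]] += config.repression_strength * deviation

    study = ExpressionStudy(
        gene_matrix=pd.DataFrame(gene_vals, index=genes, columns=list(sheet["sample_id"])),
        mirna_matrix=pd.DataFrame(mirna_vals, index=mirnas, columns=list(sheet["sample_id"])),
        samples=sheet,
        negctrl_mean=config.negctrl_mean,
        negctrl_sd=config.negctrl_sd,
    )
    truth = SyntheticTruth(
        de_gene_ids={genes[i] for i in de_gene_idx},
        de_mirna_ids={mirnas[i] for i in de_mirna_idx},
        regulator_ids={mirnas[i] for i in regulator_idx},
        regulator_targets=regulator_targets,
    )
    return study, truth


def generate_target_db(
    mirna_ids: Sequence[str],
    gene_ids: Sequence[str],
    truth: SyntheticTruth,
    decoy_density: float,
    seed: int,
) -> TargetDB:
    """Targetome containing all planted regulator targets plus random decoy links.

    Every non-planted (miRNA, gene) pair becomes a decoy target independently
    with probability ``decoy_density``; miRNAs may end up with empty target
    sets, mirroring real targetome coverage gaps.
    """
    if not 0.0 <= decoy_density <= 1.0:
        raise ValueError("decoy_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_arr = np.asarray(list(gene_ids), dtype=object)
    targets: dict[str, frozenset[str]] = {}
    for m in mirna_ids:
        planted = set(truth.regulator_targets.get(m, set()))
        if decoy_density > 0:
            hits = rng.random(gene_arr.size) < decoy_density
            planted = planted | set(gene_arr[hits])
        targets[m] = frozenset(planted)
    return TargetDB(targets=targets, background_size=len(gene_ids))


def generate_ppi(gene_ids: Sequence[str], edge_density: float, seed: int) -> nx.Graph:
    """Erdos-Renyi G(n, p) protein-interaction stand-in over the gene ids."""
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    gene_ids = list(gene_ids)
    g = nx.fast_gnp_random_graph(len(gene_ids), edge_density, seed=seed)
    return nx.relabel_nodes(g, dict(enumerate(gene_ids)))


def make_planted_loci(
    n_loci: int,
    genome_length: int,
    contig: str = "chr1",
    arm_len: int = 22,
    loop_len: int = 8,
    spacing: int = 400,
    start_offset: int = 100,
    strand: str = "+",
) -> list[PlantedLocus]:
    """Evenly spaced planted hairpin loci (mature arm = the 5p arm)."""
    loci = []
    hairpin_len = 2 * arm_len + loop_len
    for i in range(n_loci):
        s = start_offset + i * spacing
        e = s + hairpin_len
        if e > genome_length:
            raise ValueError("loci do not fit in the genome")
        loci.append(
            PlantedLocus(
                contig=contig, start=s, end=e, strand=strand,
                mature_start=s, mature_end=s + arm_len,
            )
        )
    return loci


def generate_read_set(
    loci: Sequence[PlantedLocus],
    depth: int,
    noise_reads: int,
    genome_length: int,
    seed: int,
    arm_len: int = 22,
    loop_len: int = 8,
) -> tuple[list[MappedRead], dict[str, str]]:
    """Reads piling up on planted hairpin mature arms, plus scattered noise.

    The genome carries, at each planted locus, a perfect inverted repeat
    (stem = ``arm_len`` >= 20 bp by default, loop >= 4 nt) so that an excised
    precursor folds into a hairpin.  Reads share the mature arm's 5' start
    (forming a stack) with lengths in 17-27; noise reads are scattered
    uniformly outside planted loci and kept below 10 per spurious cluster.
    """
    rng = np.random.default_rng(seed)
    contigs = sorted({lo.contig for lo in loci}) or ["chr1"]
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=genome_length)) for c in contigs
    }

    by_contig: dict[str, list[PlantedLocus]] = {}
    for lo in loci:
        for other in by_contig.get(lo.contig, []):
            if lo.start < other.end and other.start < lo.end:
                raise ValueError("planted loci overlap")
        by_contig.setdefault(lo.contig, []).append(lo)

    for lo in loci:
        if lo.end > genome_length:
            raise ValueError("locus outside genome bounds")
        alen = lo.mature_end - lo.mature_start
        arm = "".join(rng.choice(list("ACGT"), size=alen))
        loop = "".join(rng.choice(list("ACGT"), size=lo.end - lo.start - 2 * alen))
        if len(loop) < 4:
            raise ValueError("locus too short for a >= 4 nt loop")
        hairpin = arm + loop + revcomp(arm)
        g = genome[lo.contig]
        genome[lo.contig] = g[: lo.start] + hairpin + g[lo.end :]

    reads: list[MappedRead] = []
    for lo in loci:
        for _ in range(depth):
            length = int(rng.integers(20, 24))
            if lo.strand == "+":
                reads.append(
                    MappedRead(lo.contig, lo.mature_start, lo.mature_start + length, "+")
                )
            else:
                reads.append(
                    MappedRead(lo.contig, lo.mature_end - length, lo.mature_end, "-")
                )

    # scatter noise uniformly outside planted loci, rejecting placements that
    # would let any spurious single-linkage cluster (gap 10) reach 10 reads
    noise_by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    attempts = 0
    count = 0
    while count < noise_reads and attempts < noise_reads * 50 + 100:
        attempts += 1
        contig = contigs[int(rng.integers(0, len(contigs)))]
        length = int(rng.integers(17, 28))
        start = int(rng.integers(0, max(1, genome_length - length)))
        if _hits_locus(contig, start, start + length, by_contig):
            continue
        if _cluster_size_with(noise_by_contig[contig], start, start + length) >= 10:
            continue
        noise_by_contig[contig].append((start, start + length))
        reads.append(MappedRead(contig, start, start + length, "+"))
        count += 1
    return reads, genome


def _cluster_size_with(intervals: list[tuple[int, int]], start: int, end: int,
                       gap: int = 10) -> int:
    """Size of the single-linkage cluster that would contain (start, end)."""
    members = [(start, end)]
    pool = sorted(intervals)
    grown = True
    lo, hi = start, end
    while grown:
        grown = False
        remaining = []
        for s, e in pool:
            if s <= hi + gap and lo - gap <= e:
                members.append((s, e))
                lo, hi = min(lo, s), max(hi, e)
                grown = True
            else:
                remaining.append((s, e))
        pool = remaining
    return len(members)


def _hits_locus(contig: str, start: int, end: int, by_contig: dict) -> bool:
    for lo in by_contig.get(contig, []):
        if start < lo.end + 20 and lo.start - 20 < end:
            return True
    return False


def config_to_dict(config: StudyConfig) -> dict:
    return asdict(config)
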