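"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and sample sheets are TSV; targetomes are GMT; interaction
networks are SIF or two-column TSV; mapped reads are BED6 plus two extra
columns (mismatches, alignment count); genomes are FASTA; ground truth is a
JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import MappedRead, PrecursorCandidate
from .enrichment import TargetDB
from .simulate import PlantedLocus, SyntheticTruth

__all__ = [
    "read_matrix", "write_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_gmt", "write_gmt",
    "read_sif", "write_sif",
    "read_bed_reads", "write_bed_reads",
    "read_genome", "write_genome",
    "read_truth", "write_truth",
    "write_candidates",
]


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject", "timepoint", "cohort"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["timepoint"]) - {"T0", "T1"}
    if bad:
        raise ValueError(f"invalid timepoint labels: {sorted(bad)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_gmt(path, background_size: int | None = None) -> TargetDB:
    """GMT: one set per line — name, description, then member gene ids."""
    targets = {}
    universe = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            genes = [g for g in parts[2:] if g]
            targets[parts[0]] = frozenset(genes)
            universe.update(genes)
    return TargetDB(targets=targets, background_size=background_size or len(universe))


def write_gmt(targetdb: TargetDB, path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(targetdb.targets):
            members = "\t".join(sorted(targetdb.targets[mirna]))
            fh.write(f"{mirna}\tna\t{members}\n" if members else f"{mirna}\tna\n")


def read_sif(path) -> nx.Graph:
    """SIF (``a rel b``) or two-column TSV edge list; undirected simple graph."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) >= 3:
                a, b = parts[0], parts[2]
            elif len(parts) == 2:
                a, b = parts
            else:
                g.add_node(parts[0])
                continue
            if a != b:
                g.add_edge(a, b)
    return g


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
            fh.write(f"{node}\n")


def read_bed_reads(path) -> list[MappedRead]:
    """BED6 + 2 extra columns: mismatches and alignment count (0-based half-open)."""
    reads = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError("expected BED6 + mismatches + n_alignments")
            reads.append(
                MappedRead(
                    contig=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    mismatches=int(parts[6]),
                    n_alignments=int(parts[7]),
                )
            )
    return reads


def write_bed_reads(reads: Iterable[MappedRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\tread{i + 1}\t0\t{r.strand}"
                f"\t{r.mismatches}\t{r.n_alignments}\n"
            )


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "de_gene_ids": sorted(truth.de_gene_ids),
        "de_mirna_ids": sorted(truth.de_mirna_ids),
        "regulator_ids": sorted(truth.regulator_ids),
        "regulator_targets": {m: sorted(g) for m, g in truth.regulator_targets.items()},
        "planted_loci": [
            [lo.contig, lo.start, lo.end, lo.strand, lo.mature_start, lo.mature_end]
            for lo in truth.planted_loci
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        de_gene_ids=set(payload["de_gene_ids"]),
        de_mirna_ids=set(payload["de_mirna_ids"]),
        regulator_ids=set(payload["regulator_ids"]),
        regulator_targets={m: set(g) for m, g in payload["regulator_targets"].items()},
        planted_loci=[PlantedLocus(*row) for row in payload["planted_loci"]],
    )


def write_candidates(candidates: Iterable[PrecursorCandidate], tsv_path, fasta_path=None) -> None:
    rows = []
    records = []
    for i, c in enumerate(candidates):
        name = f"cand{i + 1:04d}_{c.flank_mode}"
        rows.append(
            {
                "name": name, "contig": c.contig, "start": c.start, "end": c.end,
                "strand": c.strand, "flank_mode": c.flank_mode,
                "hairpin_pass": c.hairpin_pass, "stem_len": c.stem_len,
                "loop_len": c.loop_len, "is_mitomir": c.is_mitomir,
                "clipped": c.clipped,
            }
        )
        records.append(SeqRecord(Seq(c.sequence), id=name, description=""))
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        SeqIO.write(records, str(fasta_path), "fasta")
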