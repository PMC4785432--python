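"""Novel miRNA / mitomiR prediction from genome-mapped small-RNA reads.

Filtered reads are clustered into loci; within each locus the highest local
read stack (reads sharing a 5' start) seeds excision of two candidate
precursors (50 nt upstream + 10 nt downstream of the stack, and the mirror,
emulating the 5p and 3p arm placements), which are then screened for a
miRNA-like hairpin fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MappedRead",
    "ReadLocus",
    "PrecursorCandidate",
    "preprocess_reads",
    "cluster_loci",
    "find_peak_stack",
    "excise_precursors",
    "hairpin_screen",
    "classify_mitomir",
    "discover",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

# Watson-Crick plus G.U wobble, on the RNA alphabet (T treated as U)
_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappedRead:
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int = 0
    n_alignments: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware anchor)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ReadLocus:
    contig: str
    start: int
    end: int
    strand: str
    reads: list[MappedRead]

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class PrecursorCandidate:
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    flank_mode: str  # 'up50_down10' or 'up10_down50'
    clipped: bool = False
    hairpin_pass: bool | None = None
    stem_len: int = 0
    loop_len: int = 0
    is_mitomir: bool = False
    locus: ReadLocus | None = field(default=None, repr=False)


def _overlaps(start: int, end: int, intervals: Iterable[tuple]) -> bool:
    for iv in intervals:
        if len(iv) == 3:
            _, s, e = iv
        else:
            s, e = iv
        if start < e and s < end:
            return True
    return False


def preprocess_reads(
    reads: Iterable[MappedRead],
    min_len: int = 17,
    max_len: int = 27,
    max_mismatch: int = 2,
    max_alignments: int = 6,
    ncrna_mask: dict[str, list[tuple[int, int]]] | None = None,
) -> list[MappedRead]:
    """Apply the small-RNA read filters.

    Keeps reads with length in [min_len, max_len], strictly fewer than
    ``max_mismatch`` mismatches, at most ``max_alignments`` genome alignments,
    and no overlap (by any base) with masked known ncRNA intervals.
    """
    ncrna_mask = ncrna_mask or {}
    kept = []
    for r in reads:
        if not (min_len <= r.length <= max_len):
            continue
        if r.mismatches >= max_mismatch:
            continue
        if r.n_alignments > max_alignments:
            continue
        if _overlaps(r.start, r.end, ncrna_mask.get(r.contig, [])):
            continue
        kept.append(r)
    return kept


def cluster_loci(
    reads: Iterable[MappedRead], max_gap: int = 10, min_reads: int = 10
) -> list[ReadLocus]:
    """Single-linkage clustering of reads into loci, per contig and strand.

    Reads whose intervals overlap or lie within ``max_gap`` bases merge into
    one locus; loci with fewer than ``min_reads`` reads are discarded as
    uninformative.
    """
    by_key: dict[tuple[str, str], list[MappedRead]] = {}
    for r in reads:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    loci = []
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.start, r.end))
        current: list[MappedRead] = []
        cur_end = -(10**18)
        for r in group:
            if current and r.start > cur_end + max_gap:
                if len(current) >= min_reads:
                    loci.append(_make_locus(contig, strand, current))
                current = []
                cur_end = -(10**18)
            current.append(r)
            cur_end = max(cur_end, r.end)
        if current and len(current) >= min_reads:
            loci.append(_make_locus(contig, strand, current))
    return loci


def _make_locus(contig: str, strand: str, reads: list[MappedRead]) -> ReadLocus:
    return ReadLocus(
        contig=contig,
        start=min(r.start for r in reads),
        end=max(r.end for r in reads),
        strand=strand,
        reads=list(reads),
    )


def find_peak_stack(locus: ReadLocus, window: int = 20) -> tuple[int, int, int]:
    """Locate the highest local read stack within a locus.

    A stack is the set of reads sharing a 5' start position.  Scanning from
    the 5'-most stack, the search repeatedly jumps to the highest strictly
    taller stack whose anchor lies within ``window`` bases downstream, until
    no taller stack remains in the window.  Returns the selected stack's read
    envelope ``(start, end)`` and its height (read count).
    """
    if not locus.reads:
        raise ValueError("empty locus")
    stacks: dict[int, list[MappedRead]] = {}
    for r in locus.reads:
        stacks.setdefault(r.five_prime, []).append(r)
    direction = 1 if locus.strand == "+" else -1
    anchors = sorted(stacks, key=lambda a: direction * a)
    current = anchors[0]
    while True:
        height = len(stacks[current])
        downstream = [
            a
            for a in anchors
            if 0 < (a - current) * direction <= window and len(stacks[a]) > height
        ]
        if not downstream:
            break
        # highest taller stack in window; nearest on ties
        current = max(downstream, key=lambda a: (len(stacks[a]), -(a - current) * direction))
    chosen = stacks[current]
    return (
        min(r.start for r in chosen),
        max(r.end for r in chosen),
        len(chosen),
    )


def excise_precursors(
    stack_start: int,
    stack_end: int,
    contig: str,
    strand: str,
    genome: dict[str, str],
    long_flank: int = 50,
    short_flank: int = 10,
) -> tuple[PrecursorCandidate, PrecursorCandidate]:
    """Excise the two candidate precursors around a peak stack.

    One candidate extends ``long_flank`` upstream and ``short_flank``
    downstream of the stack (placing the stack as the 3p arm) and the other is
    the mirror (5p arm).  Up/downstream are strand-aware; minus-strand
    sequences are reverse-complemented.  Intervals are clipped at contig
    edges, with the clip recorded.
    """
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not present in the genome")
    seq = genome[contig]
    clen = len(seq)

    def cut(up: int, down: int, mode: str) -> PrecursorCandidate:
        if strand == "+":
            s, e = stack_start - up, stack_end + down
        else:
            s, e = stack_start - down, stack_end + up
        clipped = s < 0 or e > clen
        s, e = max(0, s), min(clen, e)
        sub = seq[s:e]
        if strand == "-":
            sub = revcomp(sub)
        return PrecursorCandidate(
            contig=contig, start=s, end=e, strand=strand,
            sequence=sub.upper().replace("T", "U"), flank_mode=mode, clipped=clipped,
        )

    return (
        cut(long_flank, short_flank, "up50_down10"),
        cut(short_flank, long_flank, "up10_down50"),
    )


def _hairpin_dp(seq: str, min_loop: int = 3) -> tuple[int, int]:
    """Best single-hairpin chain of base pairs: returns (stem_len, loop_len).

    Maximizes the number of pairs (i1, j1), ..., (ik, jk) with
    i1 < ... < ik < jk < ... < j1 (one stem, bulges allowed) subject to a
    minimum loop of ``min_loop`` unpaired bases, over Watson-Crick and G.U
    pairs.  O(L^2) dynamic programming with traceback for the loop length.
    """
    s = seq.upper().replace("T", "U")
    L = len(s)
    M = np.zeros((L + 1, L + 1), dtype=np.int32)
    # M[i][j]: best chain using positions i..j (inclusive), i from left, j from right
    for span in range(min_loop + 2, L + 1):
        for i in range(0, L - span + 1):
            j = i + span - 1
            best = max(M[i + 1, j], M[i, j - 1])
            if (s[i], s[j]) in _PAIRS and j - i - 1 >= min_loop:
                best = max(best, M[i + 1, j - 1] + 1)
            M[i, j] = best
    stem = int(M[0, L - 1])
    if stem == 0:
        return 0, L
    # traceback for innermost pair -> loop length
    i, j = 0, L - 1
    while True:
        paired = (s[i], s[j]) in _PAIRS and j - i - 1 >= 3 and M[i, j] == M[i + 1, j - 1] + 1
        if paired and M[i + 1, j - 1] == 0:
            return stem, j - i - 1
        if paired:
            i, j = i + 1, j - 1
        elif M[i, j] == M[i + 1, j]:
            i += 1
        else:
            j -= 1


def hairpin_screen(
    sequence: str,
    min_stem: int = 16,
    max_loop: int = 20,
    folder=None,
) -> tuple[bool, int, int]:
    """Screen a candidate precursor for a miRNA-like stem-loop.

    The built-in screen counts the best single-hairpin base pairing (nested,
    no multiloop; Watson-Crick + G.U; minimum loop 3) and passes sequences
    with a stem of at least ``min_stem`` pairs and a loop of at most
    ``max_loop`` bases.  ``folder`` may supply an external structure
    predictor: a callable returning a dot-bracket string, which then replaces
    the built-in fold.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 40:
        raise ValueError("precursor candidates must be >= 40 nt")
    if set(seq) - set("ACGU"):
        raise ValueError("sequence contains non-nucleotide characters")
    if folder is not None:
        structure = folder(seq)
        stem, loop = _parse_dotbracket(structure)
    else:
        stem, loop = _hairpin_dp(seq)
    return (stem >= min_stem and loop <= max_loop), stem, loop


def _parse_dotbracket(structure: str) -> tuple[int, int]:
    """Stem and loop size of the largest hairpin in a dot-bracket string."""
    stack = []
    pairs = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if not pairs:
        return 0, len(structure)
    # hairpin loops: pairs with no pair nested inside
    inner = [(i, j) for i, j in pairs if not any(i < a and b < j for a, b in pairs)]
    i, j = min(inner, key=lambda ij: ij[1] - ij[0])
    # stem supporting that loop: chain of pairs enclosing (i, j)
    stem = sum(1 for a, b in pairs if a <= i and j <= b)
    return stem, j - i - 1


def classify_mitomir(
    locus_reads: Sequence[MappedRead],
    all_alignments: dict[tuple, list[str]] | None,
    mito_contig: str | None,
) -> bool:
    """True iff every alignment of the locus's reads is on the mitochondrial contig.

    ``all_alignments`` maps a read key ``(contig, start, end, strand)`` to the
    list of contigs of all its genome alignments; reads absent from the map
    are taken to align only where observed.
    """
    if mito_contig is None:
        warnings.warn("no mitochondrial contig declared; classify_mitomir is always False")
        return False
    all_alignments = all_alignments or {}
    for r in locus_reads:
        contigs = all_alignments.get((r.contig, r.start, r.end, r.strand), [r.contig])
        if any(c != mito_contig for c in contigs):
            return False
    return True


def discover(
    reads: Iterable[MappedRead],
    genome: dict[str, str],
    min_reads: int = 10,
    max_gap: int = 10,
    mito_contig: str | None = None,
    all_alignments: dict | None = None,
    ncrna_mask: dict | None = None,
    folder=None,
) -> list[PrecursorCandidate]:
    """Full discovery pass: filter, cluster, excise and screen.

    Returns hairpin-passing candidates, plus all mitomiR candidates regardless
    of hairpin verdict (with the verdict attached), one list entry per
    excision that passes.
    """
    filtered = preprocess_reads(reads, ncrna_mask=ncrna_mask)
    out: list[PrecursorCandidate] = []
    for locus in cluster_loci(filtered, max_gap=max_gap, min_reads=min_reads):
        s, e, _height = find_peak_stack(locus)
        cands = excise_precursors(s, e, locus.contig, locus.strand, genome)
        is_mito = (
            classify_mitomir(locus.reads, all_alignments, mito_contig)
            if mito_contig is not None
            else False
        )
        for cand in cands:
            if len(cand.sequence) < 40:
                continue
            cand.hairpin_pass, cand.stem_len, cand.loop_len = hairpin_screen(
                cand.sequence, folder=folder
            )
            cand.is_mitomir = is_mito
            cand.locus = locus
            if cand.hairpin_pass or is_mito:
                out.append(cand)
    return out
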