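"""Desk-scale exhaustive read placement and k-mer mappability.

The aligner enumerates every ungapped placement of a read on either strand
with at most ``max_mismatch`` mismatches, then applies best-stratum unique
filtering: a read is kept only if its minimal-mismatch stratum contains
exactly one placement (the semantics of bowtie's ``-m 1 --best --strata``).
Allele-specific mode is the zero-mismatch special case run against a merged
diploid genome. For genomes beyond desk scale, external aligner output can
be substituted via :func:`pirnakit.io_formats.read_alignments`.

N bases never match anything (genome N vs read N counts as a mismatch), so
assembly gaps cannot absorb reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentRecord, Assembly, revcomp
from .preprocess import SmallRNARead

__all__ = [
    "MappabilityTrack",
    "align_all",
    "filter_unique_best_stratum",
    "align_allele_specific",
    "compute_mappability",
]

# genome N -> 4, read N -> 5: the two encodings never compare equal
_GENOME_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _GENOME_CODE[ord(_b)] = _i
_READ_CODE = _GENOME_CODE.copy()
_READ_CODE[ord("N")] = 5


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MappabilityTrack:
    """Per-position k-mer uniqueness indicator for one contig.

    values[i] is 1 iff the k-mer starting at i occurs exactly once among all
    forward-strand k-mers of the genome (positions 0 .. L-k).
    """

    contig: str
    k: int
    values: np.ndarray

    @property
    def unique_fraction(self) -> float:
        return float(self.values.mean()) if len(self.values) else float("nan")


def _find_all(haystack: str, needle: str, limit: int | None = None) -> list[int]:
    """All (overlapping) occurrence starts of needle in haystack."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        if limit is not None and len(out) >= limit:
            break
        i = haystack.find(needle, i + 1)
    return out


def _placements_exact(
    seq: str, target: Assembly
) -> list[tuple[str, int, str]]:
    out: list[tuple[str, int, str]] = []
    if "N" in seq:
        # N never matches, so a read containing N has no 0-mismatch placement
        return out
    rc = revcomp(seq)
    for name, contig in target.contigs.items():
        for s in _find_all(contig, seq):
            out.append((name, s, "+"))
        # a revcomp-palindromic read legitimately places on both strands of
        # the same interval and is then multi-mapping
        for s in _find_all(contig, rc):
            out.append((name, s, "-"))
    return out


def _placements_mm(
    seq: str, genome_codes: dict[str, np.ndarray], max_mismatch: int
) -> list[tuple[str, int, str, int]]:
    """All placements with <= max_mismatch mismatches (numpy sliding windows)."""
    out = []
    fwd = _encode(seq, _READ_CODE)
    rev = _encode(revcomp(seq), _READ_CODE)
    L = len(seq)
    for name, codes in genome_codes.items():
        if L > len(codes):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        for strand, query in (("+", fwd), ("-", rev)):
            mm = (windows != query).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                out.append((name, int(pos), strand, int(mm[pos])))
    return out


def align_all(
    reads: list[SmallRNARead],
    target: Assembly,
    max_mismatch: int = 3,
) -> list[AlignmentRecord]:
    """Emit every placement of every read with <= max_mismatch mismatches.

    ``n_best`` on each emitted record is the number of placements in that
    read's minimal-mismatch stratum. A read longer than every contig simply
    yields no placements.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    records: list[AlignmentRecord] = []
    genome_codes = (
        {n: _encode(s, _GENOME_CODE) for n, s in target.contigs.items()}
        if max_mismatch > 0
        else {}
    )
    for read in reads:
        if max_mismatch == 0:
            placements = [
                (c, s, strand, 0) for c, s, strand in _placements_exact(read.sequence, target)
            ]
        else:
            placements = _placements_mm(read.sequence, genome_codes, max_mismatch)
        if not placements:
            continue
        best = min(p[3] for p in placements)
        n_best = sum(1 for p in placements if p[3] == best)
        for contig, start, strand, mm in placements:
            records.append(
                AlignmentRecord(
                    read_id=read.id,
                    target=contig,
                    start=start,
                    strand=strand,
                    read_length=len(read.sequence),
                    mismatches=mm,
                    sequence=read.sequence,
                    n_best=n_best,
                    weight=float(read.count),
                )
            )
    return records


def filter_unique_best_stratum(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep, per read, the single best-stratum placement iff it is unique.

    Reads whose minimal-mismatch stratum holds two or more placements are
    discarded entirely.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_read[rec.read_id].append(rec)
    out: list[AlignmentRecord] = []
    for recs in by_read.values():
        best = min(r.mismatches for r in recs)
        stratum = [r for r in recs if r.mismatches == best]
        if len(stratum) == 1:
            rec = stratum[0]
            rec.n_best = 1
            out.append(rec)
    return out


def align_allele_specific(
    reads: list[SmallRNARead], diploid: Assembly
) -> list[AlignmentRecord]:
    """Retain reads with exactly one perfect placement in the diploid genome.

    Mirrors mapping to a merged two-haplotype index with zero mismatches and
    unique placement required; reads from sequence shared between alleles
    place twice and are discarded, so every retained read is
    allele-informative.
    """
    out: list[AlignmentRecord] = []
    for read in reads:
        placements = _placements_exact(read.sequence, diploid)
        if len(placements) == 1:
            contig, start, strand = placements[0]
            out.append(
                AlignmentRecord(
                    read_id=read.id,
                    target=contig,
                    start=start,
                    strand=strand,
                    read_length=len(read.sequence),
                    mismatches=0,
                    sequence=read.sequence,
                    n_best=1,
                    weight=float(read.count),
                )
            )
    return out


def compute_mappability(
    genome: Assembly, k: int, collapse_revcomp: bool = False
) -> dict[str, MappabilityTrack]:
    """Indicator of genome-wide k-mer uniqueness per position.

    Counts forward-strand k-mers only by default (k=25 suits piRNA-length
    reads, k=50 mRNA/ChIP reads); ``collapse_revcomp`` additionally counts
    each k-mer's reverse complement as an occurrence.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(len(s) for s in genome.contigs.values()):
        raise ValueError("k exceeds shortest contig length")
    counts: Counter[str] = Counter()
    for seq in genome.contigs.values():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    tracks = {}
    for name, seq in genome.contigs.items():
        n = len(seq) - k + 1
        vals = np.zeros(n, dtype=np.uint8)
        for i in range(n):
            kmer = seq[i : i + k]
            c = counts[kmer]
            if collapse_revcomp:
                rc = revcomp(kmer)
                if rc != kmer:
                    c += counts[rc]
            vals[i] = 1 if c == 1 else 0
        tracks[name] = MappabilityTrack(name, k, vals)
    return tracks
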