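"""Length filtering and ncRNA contaminant subtraction for small-RNA libraries.

Inputs are pre-trimmed reads (adapter and quality trimming are delegated to
upstream tools). Identical sequences are collapsed to one record with a
count, and every downstream statistic is count-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .io_formats import Assembly, revcomp

__all__ = [
    "SmallRNARead",
    "read_small_rna",
    "collapse_reads",
    "filter_by_length",
    "subtract_ncrna",
    "write_reads_fasta",
]


@dataclass
class SmallRNARead:
    """A collapsed small-RNA read: one distinct sequence with multiplicity."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"read {self.id!r}: invalid bases")

    def __len__(self) -> int:
        return len(self.sequence)


def read_small_rna(path: str | Path, fmt: str | None = None) -> list[SmallRNARead]:
    """Read FASTA/FASTQ small-RNA reads (format inferred from suffix)."""
    if fmt is None:
        fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [
        SmallRNARead(rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), fmt)
    ]


def collapse_reads(reads: list[SmallRNARead]) -> list[SmallRNARead]:
    """Collapse identical sequences, summing counts; ids become seq_<i>."""
    totals: dict[str, int] = {}
    for r in reads:
        totals[r.sequence] = totals.get(r.sequence, 0) + r.count
    return [
        SmallRNARead(f"seq_{i}", seq, n) for i, (seq, n) in enumerate(totals.items())
    ]


def filter_by_length(
    reads: list[SmallRNARead], min_len: int = 23, max_len: int = 29
) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len (counts preserved).

    The 23-29 nt window selects the piRNA fraction; 20-29 is used for
    size-profile plots.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]


def subtract_ncrna(
    reads: list[SmallRNARead],
    contaminant_db: Assembly,
    max_mismatch: int = 0,
) -> list[SmallRNARead]:
    """Remove reads matching any rRNA/tRNA/snRNA/miRNA contaminant sequence.

    A read is removed iff it aligns within a contaminant sequence on either
    strand with at most ``max_mismatch`` mismatches (default: exact match).
    """
    if not contaminant_db.contigs:
        raise ValueError("empty contaminant database")
    if max_mismatch == 0:
        haystacks = [
            s for seq in contaminant_db.contigs.values() for s in (seq, revcomp(seq))
        ]
        return [r for r in reads if not any(r.sequence in h for h in haystacks)]
    # mismatch-tolerant path through the exhaustive aligner
    from .mapping import align_all

    hits = {
        rec.read_id
        for rec in align_all(reads, contaminant_db, max_mismatch=max_mismatch)
    }
    return [r for r in reads if r.id not in hits]


def write_reads_fasta(reads: list[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}_x{r.count}\n{r.sequence}\n")
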