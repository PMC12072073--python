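"""Readers and writers for the standard formats the pipeline touches.

All coordinates inside the package are 0-based half-open. GFF3/GTF and SAM
are 1-based in the files and are converted at the boundary; BED and bedGraph
are already 0-based half-open. The 5' end of a minus-strand alignment is the
highest genomic coordinate of its interval, which is what the ping-pong
overlap arithmetic relies on.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Assembly",
    "Feature",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_features",
    "read_alignments",
    "read_bed",
    "write_bedgraph",
    "write_sam",
    "revcomp",
]

_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Assembly:
    """An ordered set of named contig sequences (one haplotype or strain)."""

    contigs: dict[str, str]
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def non_n_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.contigs.values())


@dataclass(frozen=True)
class Feature:
    """A genomic feature in 0-based half-open coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str  # '+', '-', or '.' for strandless kinds
    kind: str  # gene, transcript, exon, CDS, UTR5, UTR3, TE, satellite, cluster
    parent: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.id!r}: bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """One placement of a read on a genome or transcript.

    ``sequence`` is in read orientation (as sequenced); for minus-strand
    placements the genomic interval is [start, start+read_length) and the 5'
    end sits at ``start + read_length - 1``.
    """

    read_id: str
    target: str
    start: int
    strand: str
    read_length: int
    mismatches: int = 0
    sequence: str = ""
    n_best: int = 1
    weight: float = 1.0  # collapsed-read multiplicity

    @property
    def end(self) -> int:
        return self.start + self.read_length

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.read_length - 1


def read_fasta(path: str | Path, source_label: str | None = None) -> Assembly:
    """Load a FASTA file into an :class:`Assembly` (sequences upper-cased).

    Record descriptions after the first whitespace are dropped; a duplicate
    record name or an empty file is a hard error.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Assembly(contigs, source_label or Path(path).stem)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_KIND_ALIASES = {
    "mRNA": "transcript",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "5UTR": "UTR5",
    "3UTR": "UTR3",
    "transposable_element": "TE",
    "satellite_DNA": "satellite",
    "piRNA_cluster": "cluster",
}


def _prefilter_gff(path: str | Path) -> str:
    """Drop records whose end precedes their start, with a warning."""
    kept: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                kept.append(line)
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 5:
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError:
                    kept.append(line)
                    continue
                if end < start:
                    warnings.warn(
                        f"rejecting feature with end < start: {line.strip()!r}", stacklevel=3
                    )
                    continue
            kept.append(line)
    return "".join(kept)


def read_features(path: str | Path, dialect: str = "gff3") -> list[Feature]:
    """Parse GFF3 or GTF into :class:`Feature` records (0-based half-open).

    Parent/child links are resolved from ``Parent`` (GFF3) or
    ``transcript_id``/``gene_id`` (GTF) attributes.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    data = _prefilter_gff(path)
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[Feature] = []
    for f in db.all_features(order_by=("seqid", "start")):
        kind = _KIND_ALIASES.get(f.featuretype, f.featuretype)
        if dialect == "gtf":
            if kind in ("gene",):
                fid = f.attributes.get("gene_id", [f.id])[0]
                parent = None
            elif kind in ("transcript",):
                fid = f.attributes.get("transcript_id", [f.id])[0]
                parent = f.attributes.get("gene_id", [None])[0]
            else:
                fid = f.id
                parent = f.attributes.get("transcript_id", [None])[0]
        else:
            fid = f.attributes.get("ID", [f.id])[0]
            parent = f.attributes.get("Parent", [None])[0]
        out.append(
            Feature(
                id=fid,
                contig=f.seqid,
                start=f.start - 1,  # GFF is 1-based inclusive
                end=f.end,
                strand=f.strand if f.strand in "+-" else ".",
                kind=kind,
                parent=parent,
            )
        )
    return out


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as GFF3 (back-converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "pirnakit",
                        {"transcript": "mRNA", "UTR5": "five_prime_UTR", "UTR3": "three_prime_UTR"}.get(
                            f.kind, f.kind
                        ),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand if f.strand in "+-" else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_alignments(path: str | Path, dialect: str = "sam") -> Iterator[AlignmentRecord]:
    """Stream mapped records from SAM/BAM as :class:`AlignmentRecord`.

    Unmapped records are skipped. Mismatch counts come from the NM tag when
    present (0 otherwise); n_best from the NH tag when present, else 1.
    Minus-strand records expose their sequence in read orientation.
    """
    mode = "rb" if dialect == "bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if not fh.references:
            raise ValueError(f"{path}: SAM/BAM header defines no reference sequences")
        for aln in fh:
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence or ""
            if aln.is_reverse and seq:
                seq = revcomp(seq.upper())
            try:
                nm = int(aln.get_tag("NM"))
            except KeyError:
                nm = 0
            try:
                nh = int(aln.get_tag("NH"))
            except KeyError:
                nh = 1
            try:
                weight = float(aln.get_tag("XW"))
            except KeyError:
                weight = 1.0
            yield AlignmentRecord(
                read_id=aln.query_name,
                target=aln.reference_name,
                start=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                read_length=aln.query_length or (aln.reference_end - aln.reference_start),
                mismatches=nm,
                sequence=seq.upper(),
                n_best=nh,
                weight=weight,
            )


def write_sam(
    records: Iterable[AlignmentRecord], assembly: Assembly, path: str | Path
) -> None:
    """Write ungapped placements as SAM (text)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in assembly.contigs.items()],
    }
    names = list(assembly.contigs)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = names.index(rec.target)
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.cigarstring = f"{rec.read_length}M"
            seq = rec.sequence or "N" * rec.read_length
            a.query_sequence = revcomp(seq) if rec.strand == "-" else seq
            a.set_tag("NM", rec.mismatches)
            a.set_tag("NH", rec.n_best)
            if rec.weight != 1.0:
                a.set_tag("XW", float(rec.weight))
            fh.write(a)


def read_bed(path: str | Path) -> list[Feature]:
    """Read BED3/BED6 regions as strand-aware features of kind 'region'."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"region_{i}"
            strand = parts[5] if len(parts) > 5 else "."
            out.append(
                Feature(
                    id=name,
                    contig=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=strand,
                    kind="region",
                )
            )
    return out


def write_bedgraph(track, path: str | Path) -> None:
    """Write a coverage-like track as bedGraph, merging runs of equal value.

    The track must expose ``contig``, ``values`` (per-position or per-bin)
    and optionally ``bin_size``. NaN values are a hard error.
    """
    import math

    values = track.values
    bin_size = getattr(track, "bin_size", 1)
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        for i, v in enumerate(values):
            v = float(v)
            if math.isnan(v):
                raise ValueError("NaN in coverage track")
            if run_val is None:
                run_start, run_val = i, v
            elif v != run_val:
                if run_val != 0:
                    fh.write(f"{track.contig}\t{run_start * bin_size}\t{i * bin_size}\t{run_val:g}\n")
                run_start, run_val = i, v
        if run_val is not None and run_val != 0:
            fh.write(
                f"{track.contig}\t{run_start * bin_size}\t{len(values) * bin_size}\t{run_val:g}\n"
            )
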