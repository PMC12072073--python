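"""Strand-resolved piRNA coverage, dual-strand cluster calling, locus
extraction with flanks, and pairwise locus structural comparison.

Cluster extent follows the "continuous mapping" idea: positions with any
piRNA coverage are merged across gaps up to ``max_gap`` and regions below a
weighted read-count floor are dropped. A cluster is dual-strand when the
minority strand carries at least ``dual_ratio_threshold`` of the majority
strand's reads.

The locus diff chains unique shared k-mers colinearly and aligns the
segments between anchors globally (edlib), yielding base-level SNP and
indel calls; an unanchorable or over-diverged segment pair (satellite
arrays, TE insertions) is reported as a single length-difference gap, which
is the dot-plot level of description.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import AlignmentRecord, Assembly, Feature

__all__ = [
    "CoverageTrack",
    "ClusterRegion",
    "Indel",
    "DiffResult",
    "stranded_coverage",
    "call_clusters",
    "extract_locus",
    "pairwise_locus_diff",
    "satellite_array_length",
    "homologous_window",
]


@dataclass
class CoverageTrack:
    contig: str
    strand: str  # '+', '-', or 'both'
    values: np.ndarray
    normalization: str = "raw"
    bin_size: int = 1


@dataclass
class ClusterRegion:
    contig: str
    start: int
    end: int
    reads_plus: float
    reads_minus: float
    dual_strand: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Indel:
    pos_a: int
    pos_b: int
    length: int
    inserted_in: str  # 'a' or 'b'


@dataclass
class DiffResult:
    snps: list[tuple[int, int, str, str]]  # (pos_a, pos_b, base_a, base_b)
    indels: list[Indel]
    gap_min: int = 500
    unalignable: bool = False

    @property
    def gaps(self) -> list[Indel]:
        return [i for i in self.indels if i.length >= self.gap_min]


def stranded_coverage(
    records: list[AlignmentRecord],
    genome: Assembly,
    multimapper_weighting: bool = False,
) -> dict[str, dict[str, CoverageTrack]]:
    """Per-base coverage per contig and strand, weighted by read counts.

    With ``multimapper_weighting`` each placement contributes weight/n_best
    ("all mappers" mode); otherwise weight is used as-is (records are
    expected to be unique-filtered).
    """
    cov = {
        name: {
            "+": np.zeros(len(seq)),
            "-": np.zeros(len(seq)),
        }
        for name, seq in genome.contigs.items()
    }
    for rec in records:
        if rec.target not in cov:
            raise ValueError(f"record on unknown contig {rec.target!r}")
        if rec.end > len(genome.contigs[rec.target]):
            raise ValueError(
                f"record {rec.read_id!r} extends past contig end (corrupt input)"
            )
        w = rec.weight / rec.n_best if multimapper_weighting else rec.weight
        cov[rec.target][rec.strand][rec.start : rec.end] += w
    return {
        name: {
            strand: CoverageTrack(name, strand, vals)
            for strand, vals in per_strand.items()
        }
        for name, per_strand in cov.items()
    }


def call_clusters(
    track_plus: CoverageTrack,
    track_minus: CoverageTrack,
    records: list[AlignmentRecord],
    min_reads: float = 100.0,
    max_gap: int = 1000,
    dual_ratio_threshold: float = 0.1,
) -> list[ClusterRegion]:
    """Merge continuously covered positions into piRNA cluster regions.

    Positions with combined coverage > 0 are merged across gaps <= max_gap;
    regions carrying fewer than ``min_reads`` weighted reads are dropped.
    """
    if track_plus.contig != track_minus.contig:
        raise ValueError("tracks must be on the same contig")
    combined = track_plus.values + track_minus.values
    covered = np.nonzero(combined > 0)[0]
    if len(covered) == 0:
        return []
    # merge covered positions across gaps <= max_gap
    breaks = np.nonzero(np.diff(covered) > max_gap)[0]
    starts = [covered[0]] + [covered[i + 1] for i in breaks]
    ends = [covered[i] + 1 for i in breaks] + [covered[-1] + 1]
    contig = track_plus.contig
    out = []
    for s, e in zip(starts, ends):
        w_plus = sum(
            r.weight
            for r in records
            if r.target == contig and r.strand == "+" and r.start < e and r.end > s
        )
        w_minus = sum(
            r.weight
            for r in records
            if r.target == contig and r.strand == "-" and r.start < e and r.end > s
        )
        if w_plus + w_minus < min_reads:
            continue
        lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
        dual = hi > 0 and (lo / hi) >= dual_ratio_threshold
        out.append(ClusterRegion(contig, int(s), int(e), w_plus, w_minus, dual))
    return out


def extract_locus(
    genome: Assembly, region: ClusterRegion | Feature, flank: int = 10_000
) -> tuple[str, int, int, bool]:
    """Cluster sequence extended by ``flank`` bp on both sides.

    Returns (sequence, start, end, truncated): coordinates of the extracted
    window, with ``truncated`` set when a flank ran into a contig edge.
    """
    seq = genome.contigs[region.contig]
    start = max(0, region.start - flank)
    end = min(len(seq), region.end + flank)
    truncated = start == 0 and region.start - flank < 0 or end == len(seq) and region.end + flank > len(seq)
    return seq[start:end], start, end, truncated


def satellite_array_length(features, contig: str | None = None) -> int:
    """Summed length of annotated satellite features (optionally per contig).

    Array-length comparisons between strains are annotation-based rather
    than diff-based, because tandem-repeat indel decomposition is not
    representation-stable.
    """
    return sum(
        f.length
        for f in features
        if f.kind == "satellite" and (contig is None or f.contig == contig)
    )


def homologous_window(
    segment: str, seq_b: str, k: int = 21, margin: int = 500
) -> tuple[int, int] | None:
    """Approximate span of ``segment``'s homolog within ``seq_b``.

    Locates k-mers unique in both sequences and returns the matched span
    extended by ``margin`` bp, or None when nothing anchors.
    """
    pos_seg = _unique_kmer_positions(segment, k)
    pos_b = _unique_kmer_positions(seq_b, k)
    hits = sorted(pos_b[m] for m in pos_seg.keys() & pos_b.keys())
    if not hits:
        return None
    return max(0, hits[0] - margin), min(len(seq_b), hits[-1] + k + margin)


# --- pairwise locus diff -------------------------------------------------


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in pos:
            del pos[kmer]
            dup.add(kmer)
        else:
            pos[kmer] = i
    return pos


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest colinear chain (LIS on pos_b after sorting by pos_a)."""
    anchors.sort()
    tails: list[int] = []  # pos_b values
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        chain.append(anchors[i])
        i = prev[i]
    return chain[::-1]


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _align_segment(
    a_seg: str,
    b_seg: str,
    off_a: int,
    off_b: int,
    result: DiffResult,
    max_divergence: float,
) -> None:
    """Globally align one inter-anchor segment pair and collect calls."""
    if not a_seg and not b_seg:
        return
    if not b_seg:
        result.indels.append(Indel(off_a, off_b, len(a_seg), "a"))
        return
    if not a_seg:
        result.indels.append(Indel(off_a, off_b, len(b_seg), "b"))
        return
    aln = edlib.align(a_seg, b_seg, mode="NW", task="path")
    aligned_span = min(len(a_seg), len(b_seg))
    substitutions = aln["editDistance"] - abs(len(a_seg) - len(b_seg))
    # divergence bailout applies to long unanchored segments only; a short
    # inter-anchor segment holding a single variant is always base-aligned
    if aligned_span >= 100 and substitutions / aligned_span > max_divergence:
        # over-diverged (unanchored repeat/TE material): dot-plot level gap
        if len(a_seg) != len(b_seg):
            longer = "a" if len(a_seg) > len(b_seg) else "b"
            result.indels.append(
                Indel(off_a, off_b, abs(len(a_seg) - len(b_seg)), longer)
            )
        return
    i = j = 0  # offsets within a_seg / b_seg
    for n, op in _parse_cigar(aln["cigar"]):
        if op == "=":
            i += n
            j += n
        elif op == "X":
            for t in range(n):
                result.snps.append(
                    (off_a + i + t, off_b + j + t, a_seg[i + t], b_seg[j + t])
                )
            i += n
            j += n
        elif op == "I":  # bases present only in a (query)
            result.indels.append(Indel(off_a + i, off_b + j, n, "a"))
            i += n
        elif op == "D":  # bases present only in b (target)
            result.indels.append(Indel(off_a + i, off_b + j, n, "b"))
            j += n


def pairwise_locus_diff(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    gap_min: int = 500,
    max_divergence: float = 0.10,
) -> DiffResult:
    """Colinear SNP/indel/gap calls between two homologous locus sequences.

    Anchors are k-mers unique in both sequences, chained colinearly;
    segments between successive anchors are aligned globally. Indels of
    length >= gap_min are additionally exposed as ``gaps`` (TE-insertion
    scale). Sequence pairs without any colinear anchor chain are flagged
    unalignable.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    result = DiffResult(snps=[], indels=[], gap_min=gap_min)
    if seq_a == seq_b:
        return result
    pos_a = _unique_kmer_positions(seq_a, k)
    pos_b = _unique_kmer_positions(seq_b, k)
    anchors = [(pos_a[m], pos_b[m]) for m in pos_a.keys() & pos_b.keys()]
    if not anchors:
        result.unalignable = True
        return result
    chain = _chain_anchors(anchors)
    # thin to mutually non-overlapping anchors so inter-anchor segments in
    # the two sequences stay in register
    thinned: list[tuple[int, int]] = []
    for a, b in chain:
        if not thinned or (a >= thinned[-1][0] + k and b >= thinned[-1][1] + k):
            thinned.append((a, b))
    chain = thinned
    prev_a = prev_b = 0
    for a, b in chain:
        _align_segment(
            seq_a[prev_a:a], seq_b[prev_b:b], prev_a, prev_b, result, max_divergence
        )
        prev_a, prev_b = a + k, b + k
    _align_segment(
        seq_a[prev_a:], seq_b[prev_b:], prev_a, prev_b, result, max_divergence
    )
    result.snps.sort()
    result.indels.sort(key=lambda i: i.pos_a)
    return result
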