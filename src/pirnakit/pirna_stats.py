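"""Per-locus piRNA statistics: orientation split, size profile, 1U/10A
nucleotide bias, the ping-pong signature with its Z-score, and RPKM.

The ping-pong signature counts 5'-overlap pairs between plus- and
minus-strand piRNAs. For a plus-strand 5' end at p+ and a minus-strand 5'
end at p- the overlap is o = p- - p+ + 1; the histogram over o in
[1, max_overlap] is weighted by the product of collapsed-read counts at the
two 5' positions, and the Z-score of the 10-nt bin is taken against the
mean and sample standard deviation of all other bins. An excess at o = 10
is the hallmark of the Aub/Ago3 amplification cycle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, Feature
from .preprocess import SmallRNARead

__all__ = [
    "OrientationSplit",
    "NucleotideBias",
    "PingPongResult",
    "ExpressionValue",
    "split_orientation",
    "size_distribution",
    "nucleotide_bias",
    "pingpong_signature",
    "count_feature_reads",
    "rpkm",
    "fold_change",
]


@dataclass
class OrientationSplit:
    sense: list[AlignmentRecord]
    antisense: list[AlignmentRecord]

    @property
    def n_sense(self) -> float:
        return sum(r.weight for r in self.sense)

    @property
    def n_antisense(self) -> float:
        return sum(r.weight for r in self.antisense)


@dataclass
class NucleotideBias:
    """Count-weighted fraction of reads with 5' U and position-10 A."""

    frac_1U: float
    frac_10A: float
    n: float
    defined: bool = True


@dataclass
class PingPongResult:
    histogram: dict[int, float]
    z10: float  # NaN when undefined
    flag: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.z10)


@dataclass
class ExpressionValue:
    feature_id: str
    count: float
    rpkm: float
    library_size: float


def split_orientation(
    records: list[AlignmentRecord], feature: Feature
) -> OrientationSplit:
    """Partition records into sense/antisense relative to a stranded feature."""
    if feature.strand not in "+-":
        raise ValueError(f"feature {feature.id!r} has no strand")
    sense = [r for r in records if r.strand == feature.strand]
    anti = [r for r in records if r.strand != feature.strand]
    return OrientationSplit(sense, anti)


def size_distribution(
    reads: list[SmallRNARead] | list[AlignmentRecord],
    min_len: int = 20,
    max_len: int = 29,
) -> dict[int, float]:
    """Count-weighted read-length histogram with all bins present."""
    hist = {length: 0.0 for length in range(min_len, max_len + 1)}
    for r in reads:
        length = len(r.sequence) if hasattr(r, "sequence") and r.sequence else r.read_length
        if min_len <= length <= max_len:
            hist[length] += getattr(r, "weight", None) or getattr(r, "count", 1)
    return hist


def nucleotide_bias(records: list[AlignmentRecord] | list[SmallRNARead]) -> NucleotideBias:
    """1U / 10A fractions over read-orientation sequences (T counts as U).

    frac_10A is computed over reads of length >= 10 only, since position 10
    does not exist on shorter reads.
    """
    n = 0.0
    n1u = 0.0
    n10 = 0.0
    n10a = 0.0
    for r in records:
        seq = r.sequence
        w = float(getattr(r, "weight", None) or getattr(r, "count", 1))
        n += w
        if seq[0] == "T":
            n1u += w
        if len(seq) >= 10:
            n10 += w
            if seq[9] == "A":
                n10a += w
    if n == 0:
        return NucleotideBias(float("nan"), float("nan"), 0.0, defined=False)
    return NucleotideBias(
        frac_1U=n1u / n,
        frac_10A=n10a / n10 if n10 > 0 else float("nan"),
        n=n,
    )


def pingpong_signature(
    records: list[AlignmentRecord], max_overlap: int = 20
) -> PingPongResult:
    """5'-overlap histogram between opposite-strand piRNAs and its Z-score.

    Weighting is the product of summed collapsed-read counts at the two 5'
    positions. z10 is undefined (NaN, flagged) when no pair exists or the
    non-10 background bins have zero spread.
    """
    plus: dict[tuple[str, int], float] = defaultdict(float)
    minus: dict[tuple[str, int], float] = defaultdict(float)
    for r in records:
        key = (r.target, r.five_prime)
        if r.strand == "+":
            plus[key] += r.weight
        else:
            minus[key] += r.weight
    hist = {o: 0.0 for o in range(1, max_overlap + 1)}
    for (contig, p_plus), w_plus in plus.items():
        for o in range(1, max_overlap + 1):
            w_minus = minus.get((contig, p_plus + o - 1))
            if w_minus:
                hist[o] += w_plus * w_minus
    if all(v == 0 for v in hist.values()):
        return PingPongResult(hist, float("nan"), flag="no complementary pairs")
    background = np.array([v for o, v in hist.items() if o != 10], dtype=float)
    sd = background.std(ddof=1)
    if sd == 0:
        return PingPongResult(hist, float("nan"), flag="zero background spread")
    z10 = (hist[10] - background.mean()) / sd
    return PingPongResult(hist, float(z10))


def count_feature_reads(
    records: list[AlignmentRecord], features: list[Feature]
) -> tuple[dict[str, float], float, float]:
    """Assign records to features by exon overlap.

    A record counts toward a feature iff its interval overlaps an exon of
    that feature; records overlapping exons of two or more features are
    dropped as ambiguous. Features without exon children count over their
    own span. Returns (counts per feature id, unassigned weight, ambiguous
    weight); the three components sum to the total input weight.
    """
    parent_of: dict[str, str] = {}
    for f in features:
        parent_of[f.id] = f.parent or f.id

    def top(fid: str) -> str:
        seen = set()
        while parent_of.get(fid, fid) != fid and fid not in seen:
            seen.add(fid)
            fid = parent_of[fid]
        return fid

    roots = {top(f.id) for f in features}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    has_exons = {top(f.id) for f in features if f.kind == "exon"}
    for f in features:
        if f.kind == "exon":
            trees[f.contig].addi(f.start, f.end, top(f.id))
        elif f.id in roots and f.id not in has_exons:
            trees[f.contig].addi(f.start, f.end, f.id)

    counts: dict[str, float] = {fid: 0.0 for fid in roots}
    unassigned = 0.0
    ambiguous = 0.0
    for rec in records:
        hits = {iv.data for iv in trees[rec.target].overlap(rec.start, rec.end)}
        if not hits:
            unassigned += rec.weight
        elif len(hits) > 1:
            ambiguous += rec.weight
        else:
            counts[hits.pop()] += rec.weight
    return counts, unassigned, ambiguous


def rpkm(count: float, feature_length: int, library_size: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0 or library_size <= 0:
        raise ValueError("feature_length and library_size must be positive")
    return count * 1e9 / (feature_length * library_size)


def fold_change(rpkm_a: float, rpkm_b: float, pseudocount: float = 0.0) -> float:
    """(a + p) / (b + p); NaN (flagged by the caller) when undefined at p=0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num, den = rpkm_a + pseudocount, rpkm_b + pseudocount
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den
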