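"""Seeded generators for strain-genome pairs and sequencing libraries with
complete ground truth.

The generator emulates the structure of the studied system: two diverged
strain genomes where one carries a ~5.4 kb LTR-retroelement insertion
upstream of a gene inside a dual-strand piRNA cluster, satellite arrays
flanking the cluster (370 bp and 36 bp unit analogues), SNPs, one planted
multi-bp indel, and scattered short indels; piRNA libraries with
controllable ping-pong fraction and 1U/10A bias plus ncRNA contaminants and
genomic background; maternal-deposition hybrid libraries with a
controllable minor-allele read fraction; and ChIP treat/input fragment
libraries with controllable enrichment over chosen regions. Every read and
every planted variant is recorded in a truth table, so each pipeline stage
can be tested against known answers without external data.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io_formats import AlignmentRecord, Assembly, Feature, revcomp
from .preprocess import SmallRNARead

__all__ = [
    "SatelliteConfig",
    "GenomeConfig",
    "DivergenceConfig",
    "PirnaConfig",
    "HybridConfig",
    "ChipConfig",
    "SimulationConfig",
    "ReadLabel",
    "TruthSet",
    "synthetic_contaminants",
    "generate_genome_pair",
    "simulate_pirna_library",
    "simulate_hybrid_library",
    "simulate_chip_library",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SatelliteConfig:
    unit_length: int = 370  # pvB370-analogue monomer
    copies_a: int = 30
    copies_b: int = 10  # ~3-fold shorter array in the naive strain


@dataclass
class GenomeConfig:
    n_contigs: int = 1
    contig_length: int = 100_000
    gc: float = 0.40  # AT-rich, as in Drosophila heterochromatin


@dataclass
class DivergenceConfig:
    snp_rate: float = 0.01
    indel_rate: float = 1e-4  # short scattered 1-6 bp indels
    planted_indel_lengths: tuple[int, ...] = (69,)
    te_insertion_length: int = 5403  # Gypsy-scale LTR element, strain A only
    satellite: SatelliteConfig = field(default_factory=SatelliteConfig)


@dataclass
class PirnaConfig:
    cluster_span: int = 20_000
    n_reads: int = 10_000  # primary reads; partners come on top
    pingpong_fraction: float = 0.3
    frac_1U: float = 0.88
    frac_10A: float = 0.6
    length_mean: float = 26.0
    length_sd: float = 1.5
    contaminant_fraction: float = 0.05
    background_rate: float = 0.01


@dataclass
class HybridConfig:
    minor_allele_fraction: float = 0.054
    n_reads: int = 20_000


@dataclass
class ChipConfig:
    enrichment_fold: float = 8.0
    fragment_length: int = 200
    n_fragments: int = 20_000


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    pirna: PirnaConfig = field(default_factory=PirnaConfig)
    hybrid: HybridConfig = field(default_factory=HybridConfig)
    chip: ChipConfig = field(default_factory=ChipConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        sat = SatelliteConfig(**d.get("divergence", {}).pop("satellite", {})) if "divergence" in d else SatelliteConfig()
        div = d.get("divergence", {})
        if "planted_indel_lengths" in div:
            div["planted_indel_lengths"] = tuple(div["planted_indel_lengths"])
        return cls(
            seed=d.get("seed", 0),
            genome=GenomeConfig(**d.get("genome", {})),
            divergence=DivergenceConfig(satellite=sat, **div),
            pirna=PirnaConfig(**d.get("pirna", {})),
            hybrid=HybridConfig(**d.get("hybrid", {})),
            chip=ChipConfig(**d.get("chip", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReadLabel:
    read_id: str
    origin: str  # source assembly label, or 'contaminant'
    contig: str
    strand: str
    five_prime: int
    length: int
    is_pingpong_partner: bool = False
    is_contaminant: bool = False
    is_background: bool = False


@dataclass
class TruthSet:
    """Planted variants and per-read labels for one simulation."""

    snps: list[tuple[int, int, str, str]] = field(default_factory=list)
    indels: list[tuple[int, int, int, str]] = field(default_factory=list)  # pos_a,pos_b,len,inserted_in
    planted_indels: list[tuple[int, int, int, str]] = field(default_factory=list)
    te: tuple[int, int] | None = None  # (pos_a, length), present in A only
    cluster_a: Feature | None = None
    cluster_b: Feature | None = None
    read_labels: dict[str, ReadLabel] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def synthetic_contaminants(seed: int = 104729) -> Assembly:
    """A small synthetic ncRNA set (rRNA/tRNA/snRNA/miRNA labels).

    Sequences are random under a fixed internal seed; they are stand-ins for
    a real contaminant library, adequate for exercising subtraction logic.
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    for name, length, n in (
        ("rRNA", 1500, 4),
        ("tRNA", 75, 8),
        ("snRNA", 150, 4),
        ("miRNA", 22, 8),
    ):
        for i in range(n):
            contigs[f"synthetic_{name}_{i + 1}"] = _random_seq(rng, length, gc=0.5)
    return Assembly(contigs, source_label="synthetic_ncRNA")


# --- genome pair ---------------------------------------------------------


def _mutate_part(
    seq: str,
    rng: np.random.Generator,
    snp_rate: float,
    indel_rate: float,
    min_space: int = 25,
):
    """Derive the strain-B version of a shared segment.

    Edits (substitutions and 1-6 bp indels) are spaced at least ``min_space``
    bp apart and away from the segment edges so each variant sits in
    unambiguous alignable context. Returns (seq_b, snps, indels) with
    part-relative (pos_a, pos_b) coordinates.
    """
    n = len(seq)
    n_snp = rng.binomial(n, snp_rate)
    n_ind = rng.binomial(n, indel_rate)
    n_events = min(n_snp + n_ind, max(0, n - 2 * min_space))
    if n > 2 * min_space and n_events > 0:
        candidates = rng.choice(
            np.arange(min_space, n - min_space), size=n_events, replace=False
        )
    else:
        candidates = np.array([], dtype=int)
    kinds = np.array(["snp"] * n_snp + ["indel"] * n_ind)[:n_events]
    rng.shuffle(kinds)
    events = sorted(zip(candidates.tolist(), kinds.tolist()))
    # enforce spacing
    spaced: list[tuple[int, str]] = []
    for pos, kind in events:
        if not spaced or pos - spaced[-1][0] >= min_space:
            spaced.append((pos, kind))
    out: list[str] = []
    snps: list[tuple[int, int, str, str]] = []
    indels: list[tuple[int, int, int, str]] = []
    prev = 0
    j = 0  # running length of B
    for pos, kind in spaced:
        out.append(seq[prev:pos])
        j += pos - prev
        if kind == "snp":
            alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            snps.append((pos, j, seq[pos], alt))
            out.append(alt)
            prev = pos + 1
            j += 1
        else:
            L = int(rng.integers(1, 7))
            if rng.random() < 0.5 and pos + L <= n - min_space:
                # bases present in A only
                indels.append((pos, j, L, "a"))
                prev = pos + L
            else:
                ins = _random_seq(rng, L)
                indels.append((pos, j, L, "b"))
                out.append(ins)
                j += L
                prev = pos
    out.append(seq[prev:])
    return "".join(out), snps, indels


def generate_genome_pair(
    config: SimulationConfig,
) -> tuple[Assembly, Assembly, dict[str, list[Feature]], TruthSet]:
    """Build the diverged strain pair with a planted TE insertion.

    Strain A carries the TE insertion immediately upstream of the gene and
    the longer satellite array; strain B differs by SNPs at ``snp_rate``,
    scattered short indels, the planted indel(s), the missing TE, and the
    resized satellite array. Returns (assembly_a, assembly_b, annotations
    per strain label, truth).
    """
    rng = np.random.default_rng(config.seed)
    g, d, p = config.genome, config.divergence, config.pirna
    sat = d.satellite
    unit1 = _random_seq(rng, sat.unit_length)
    unit2 = _random_seq(rng, 36)
    te_seq = _random_seq(rng, d.te_insertion_length) if d.te_insertion_length else ""

    fixed = (
        sat.unit_length * max(sat.copies_a, sat.copies_b)
        + 36 * 20
        + len(te_seq)
        + p.cluster_span
        + 2 * 1000
        + sum(d.planted_indel_lengths)
    )
    flank = (g.contig_length - fixed) // 2
    if flank < 1000:
        raise ValueError("contig_length too small for the configured components")

    mut = lambda s: _mutate_part(s, rng, d.snp_rate, d.indel_rate)

    # parts: (name, seq_a, seq_b, snps_rel, indels_rel)
    parts: list[tuple[str, str, str, list, list]] = []

    def shared(name: str, seq: str) -> None:
        sb, snps, indels = mut(seq)
        parts.append((name, seq, sb, snps, indels))

    def planted(name: str, seq_a: str, seq_b: str) -> None:
        parts.append((name, seq_a, seq_b, [], []))

    shared("left_flank", _random_seq(rng, flank, g.gc))
    planted("sat1", unit1 * sat.copies_a, unit1 * sat.copies_b)
    shared("intergenic_up", _random_seq(rng, 1000, g.gc))
    planted("te", te_seq, "")
    shared("cluster_core", _random_seq(rng, p.cluster_span, g.gc))
    half = _random_seq(rng, 500, g.gc)
    shared("intergenic_down_1", half)
    for i, L in enumerate(d.planted_indel_lengths):
        planted(f"planted_indel_{i}", _random_seq(rng, L, g.gc), "")
        shared(f"intergenic_down_sp_{i}", _random_seq(rng, 500, g.gc))
    planted("sat2", unit2 * 20, unit2 * 20)
    shared("right_flank", _random_seq(rng, flank, g.gc))

    truth = TruthSet()
    seq_a_parts: list[str] = []
    seq_b_parts: list[str] = []
    off_a = off_b = 0
    offsets: dict[str, tuple[int, int, int, int]] = {}
    for name, sa, sb, snps, indels in parts:
        offsets[name] = (off_a, off_b, len(sa), len(sb))
        for pa, pb, ba, bb in snps:
            truth.snps.append((off_a + pa, off_b + pb, ba, bb))
        for pa, pb, L, side in indels:
            truth.indels.append((off_a + pa, off_b + pb, L, side))
        if name == "te" and sa:
            truth.te = (off_a, len(sa))
            truth.indels.append((off_a, off_b, len(sa), "a"))
        if name.startswith("planted_indel"):
            truth.planted_indels.append((off_a, off_b, len(sa), "a"))
            truth.indels.append((off_a, off_b, len(sa), "a"))
        seq_a_parts.append(sa)
        seq_b_parts.append(sb)
        off_a += len(sa)
        off_b += len(sb)

    contig = "contig_1"
    contigs_a = {contig: "".join(seq_a_parts)}
    contigs_b = {contig: "".join(seq_b_parts)}
    for i in range(1, g.n_contigs):
        extra = _random_seq(rng, g.contig_length, g.gc)
        contigs_a[f"contig_{i + 1}"] = extra
        contigs_b[f"contig_{i + 1}"] = extra  # undiverged spare contigs
    asm_a = Assembly(contigs_a, source_label="strainA")
    asm_b = Assembly(contigs_b, source_label="strainB")

    ca0, cb0, ca_len, cb_len = offsets["cluster_core"]
    truth.cluster_a = Feature("cluster", contig, ca0, ca0 + ca_len, "+", "cluster")
    truth.cluster_b = Feature("cluster", contig, cb0, cb0 + cb_len, "+", "cluster")

    # gene model inside the cluster core (strain A coordinates)
    gs = ca0 + 2000
    annotations: dict[str, list[Feature]] = {"strainA": [], "strainB": []}
    utr5, cds1, intron, cds2, utr3 = 400, 1500, 500, 1500, 400
    ge = gs + utr5 + cds1 + intron + cds2 + utr3
    ann_a = annotations["strainA"]
    ann_a.append(truth.cluster_a)
    ann_a.append(Feature("gene1", contig, gs, ge, "+", "gene"))
    ann_a.append(Feature("gene1.t1", contig, gs, ge, "+", "transcript", parent="gene1"))
    ann_a.append(Feature("gene1.t1.e1", contig, gs, gs + utr5 + cds1, "+", "exon", parent="gene1.t1"))
    ann_a.append(
        Feature("gene1.t1.e2", contig, gs + utr5 + cds1 + intron, ge, "+", "exon", parent="gene1.t1")
    )
    ann_a.append(Feature("gene1.t1.utr5", contig, gs, gs + utr5, "+", "UTR5", parent="gene1.t1"))
    ann_a.append(Feature("gene1.t1.cds1", contig, gs + utr5, gs + utr5 + cds1, "+", "CDS", parent="gene1.t1"))
    ann_a.append(
        Feature("gene1.t1.cds2", contig, gs + utr5 + cds1 + intron, ge - utr3, "+", "CDS", parent="gene1.t1")
    )
    ann_a.append(Feature("gene1.t1.utr3", contig, ge - utr3, ge, "+", "UTR3", parent="gene1.t1"))
    if truth.te:
        ann_a.append(Feature("te_gypsy_like", contig, truth.te[0], truth.te[0] + truth.te[1], "+", "TE"))
    for label, key in (("strainA", 0), ("strainB", 1)):
        s1 = offsets["sat1"]
        s2 = offsets["sat2"]
        off = s1[key]
        length = s1[2] if key == 0 else s1[3]
        annotations[label].append(
            Feature("sat_370_array", contig, off, off + length, ".", "satellite")
        )
        off = s2[key]
        length = s2[2] if key == 0 else s2[3]
        annotations[label].append(
            Feature("sat_36_array", contig, off, off + length, ".", "satellite")
        )
    annotations["strainB"].insert(0, truth.cluster_b)
    return asm_a, asm_b, annotations, truth


# --- read libraries ------------------------------------------------------


def _draw_length(rng: np.random.Generator, cfg: PirnaConfig) -> int:
    return int(np.clip(round(rng.normal(cfg.length_mean, cfg.length_sd)), 23, 29))


def _read_at(genome_seq: str, five_prime: int, length: int, strand: str) -> str:
    if strand == "+":
        return genome_seq[five_prime : five_prime + length]
    return revcomp(genome_seq[five_prime - length + 1 : five_prime + 1])


def _with_base(seq: str, pos: int, base: str, rng: np.random.Generator, prob: float) -> str:
    """Set seq[pos] to ``base`` with probability prob, else a uniform other base."""
    if len(seq) <= pos:
        return seq
    new = base if rng.random() < prob else str(rng.choice([b for b in "ACGT" if b != base]))
    return seq[:pos] + new + seq[pos + 1 :]


def simulate_pirna_library(
    genome: Assembly,
    cluster: Feature,
    config: PirnaConfig,
    seed: int = 0,
) -> tuple[list[SmallRNARead], TruthSet]:
    """Dual-strand piRNA library over one cluster with ground truth.

    Primary reads have uniform 5' ends on both strands of the cluster; each
    primary spawns an opposite-strand partner with an exact 10-nt 5' overlap
    with probability ``pingpong_fraction``. The 5' base of primaries is U
    (T) with probability ``frac_1U`` and the 10th base of partners is A with
    probability ``frac_10A`` (a uniformly chosen other base otherwise, so
    the configured probability is exactly the expected fraction). ncRNA
    contaminants and genome-wide background reads are mixed in at their
    configured rates.
    """
    rng = np.random.default_rng(seed)
    seq = genome.contigs[cluster.contig]
    max_len = 29
    if cluster.length <= max_len:
        raise ValueError("cluster shorter than the maximum read length")
    truth = TruthSet(cluster_a=cluster)
    reads: list[SmallRNARead] = []

    def emit(label: ReadLabel, sequence: str) -> None:
        reads.append(SmallRNARead(label.read_id, sequence))
        truth.read_labels[label.read_id] = label

    idx = 0
    for _ in range(config.n_reads):
        L = _draw_length(rng, config)
        strand = "+" if rng.random() < 0.5 else "-"
        lo = cluster.start + (L - 1 if strand == "-" else 0)
        hi = cluster.end - (L if strand == "+" else 1)
        p5 = int(rng.integers(lo, hi))
        s = _with_base(_read_at(seq, p5, L, strand), 0, "T", rng, config.frac_1U)
        emit(ReadLabel(f"sim_{idx}", genome.source_label, cluster.contig, strand, p5, L), s)
        idx += 1
        if rng.random() < config.pingpong_fraction:
            Lp = _draw_length(rng, config)
            if strand == "+":
                q5, qstrand = p5 + 9, "-"
            else:
                q5, qstrand = p5 - 9, "+"
            edge = q5 - Lp + 1 if qstrand == "-" else q5 + Lp
            if 0 <= q5 < len(seq) and 0 <= edge <= len(seq):
                sp = _with_base(_read_at(seq, q5, Lp, qstrand), 9, "A", rng, config.frac_10A)
                emit(
                    ReadLabel(
                        f"sim_{idx}", genome.source_label, cluster.contig, qstrand, q5, Lp,
                        is_pingpong_partner=True,
                    ),
                    sp,
                )
                idx += 1
    n_core = len(reads)
    n_background = rng.binomial(n_core, config.background_rate)
    contig_names = list(genome.contigs)
    for _ in range(n_background):
        cname = contig_names[int(rng.integers(len(contig_names)))]
        cseq = genome.contigs[cname]
        L = _draw_length(rng, config)
        strand = "+" if rng.random() < 0.5 else "-"
        p5 = int(rng.integers(L - 1, len(cseq) - L))
        emit(
            ReadLabel(f"sim_{idx}", genome.source_label, cname, strand, p5, L, is_background=True),
            _read_at(cseq, p5, L, strand),
        )
        idx += 1
    cf = config.contaminant_fraction
    if cf > 0:
        db = synthetic_contaminants()
        names = [n for n, s in db.contigs.items() if len(s) >= 29]
        n_cont = round(cf / (1 - cf) * len(reads))
        for _ in range(n_cont):
            cname = names[int(rng.integers(len(names)))]
            cseq = db.contigs[cname]
            L = _draw_length(rng, config)
            start = int(rng.integers(0, len(cseq) - L + 1))
            emit(
                ReadLabel(f"sim_{idx}", "contaminant", cname, "+", start, L, is_contaminant=True),
                cseq[start : start + L],
            )
            idx += 1
    return reads, truth


def records_from_truth(
    truth: TruthSet,
    reads: list[SmallRNARead] | None = None,
    include_background: bool = False,
) -> list[AlignmentRecord]:
    """Genome placements reconstructed from truth labels (skips contaminants).

    Useful for exercising downstream statistics at their true positions
    without re-running the aligner.
    """
    seq_of = {r.id: r.sequence for r in reads} if reads else {}
    out = []
    for lab in truth.read_labels.values():
        if lab.is_contaminant or (lab.is_background and not include_background):
            continue
        start = lab.five_prime if lab.strand == "+" else lab.five_prime - lab.length + 1
        out.append(
            AlignmentRecord(
                read_id=lab.read_id,
                target=lab.contig,
                start=start,
                strand=lab.strand,
                read_length=lab.length,
                sequence=seq_of.get(lab.read_id, ""),
                weight=1.0,
            )
        )
    return out


def simulate_hybrid_library(
    genome_a: Assembly,
    genome_b: Assembly,
    cluster_a: Feature,
    cluster_b: Feature,
    config: HybridConfig,
    pirna: PirnaConfig | None = None,
    seed: int = 0,
) -> tuple[list[SmallRNARead], TruthSet]:
    """Error-free hybrid-ovary library drawn from two alleles of one locus.

    Each read originates from allele B with probability
    ``minor_allele_fraction`` (0 models the no-maternal-deposition cross),
    else from allele A; reads are exact genome substrings so the perfect-
    unique diploid filter assigns every retained read to its true allele.
    """
    rng = np.random.default_rng(seed)
    pirna = pirna or PirnaConfig()
    truth = TruthSet(cluster_a=cluster_a, cluster_b=cluster_b)
    reads: list[SmallRNARead] = []
    for i in range(config.n_reads):
        from_b = rng.random() < config.minor_allele_fraction
        genome, cluster = (genome_b, cluster_b) if from_b else (genome_a, cluster_a)
        seq = genome.contigs[cluster.contig]
        L = _draw_length(rng, pirna)
        strand = "+" if rng.random() < 0.5 else "-"
        lo = cluster.start + (L - 1 if strand == "-" else 0)
        hi = cluster.end - (L if strand == "+" else 1)
        p5 = int(rng.integers(lo, hi))
        rid = f"hyb_{i}"
        reads.append(SmallRNARead(rid, _read_at(seq, p5, L, strand)))
        truth.read_labels[rid] = ReadLabel(
            rid, genome.source_label, cluster.contig, strand, p5, L
        )
    return reads, truth


def simulate_chip_library(
    genome: Assembly,
    regions: list[Feature],
    config: ChipConfig,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Treat/input fragment libraries with planted enrichment.

    Input fragment starts are uniform over each contig; treat start density
    is multiplied by ``enrichment_fold`` inside the given regions. Fragment
    length is fixed. Returns (treat, input) records.
    """
    rng = np.random.default_rng(seed)
    treat: list[AlignmentRecord] = []
    input_: list[AlignmentRecord] = []
    contig_names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contig_names], dtype=float)
    contig_p = lengths / lengths.sum()
    flen = config.fragment_length
    # per-contig start weights for treat
    weights = {}
    for name in contig_names:
        L = len(genome.contigs[name])
        n_start = max(1, L - flen + 1)
        w = np.ones(n_start)
        for reg in regions:
            if reg.contig == name:
                w[max(0, reg.start) : min(n_start, reg.end)] = config.enrichment_fold
        weights[name] = w / w.sum()
    for kind, bucket in (("treat", treat), ("input", input_)):
        picks = rng.choice(len(contig_names), size=config.n_fragments, p=contig_p)
        counts = np.bincount(picks, minlength=len(contig_names))
        i = 0
        for ci, n_frag in enumerate(counts):
            if n_frag == 0:
                continue
            name = contig_names[ci]
            n_start = max(1, len(genome.contigs[name]) - flen + 1)
            if kind == "treat":
                starts = rng.choice(n_start, size=n_frag, p=weights[name])
            else:
                starts = rng.integers(0, n_start, size=n_frag)
            for start in starts:
                bucket.append(
                    AlignmentRecord(
                        read_id=f"{kind}_{i}",
                        target=name,
                        start=int(start),
                        strand="+",
                        read_length=flen,
                    )
                )
                i += 1
    return treat, input_
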