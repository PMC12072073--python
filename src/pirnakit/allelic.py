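"""Diploid-genome construction and allele-of-origin piRNA accounting.

Merging two strain assemblies into one "diploid" reference and demanding a
single perfect placement per read makes every retained read
allele-informative: reads from sequence identical between the haplotypes
place twice and are discarded. Percentages over a homologous locus pair
then measure the relative piRNA output of the two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentRecord, Assembly, Feature

__all__ = ["AllelicCounts", "build_diploid", "allelic_counts", "informative_fraction"]

SEPARATOR = "|"


@dataclass
class AllelicCounts:
    locus_id: str
    count_allele_a: float
    count_allele_b: float
    rpkm_a: float = float("nan")
    rpkm_b: float = float("nan")
    defined: bool = True

    @property
    def total(self) -> float:
        return self.count_allele_a + self.count_allele_b

    @property
    def pct_a(self) -> float:
        return 100.0 * self.count_allele_a / self.total if self.total > 0 else float("nan")

    @property
    def pct_b(self) -> float:
        return 100.0 * self.count_allele_b / self.total if self.total > 0 else float("nan")


def build_diploid(assembly_a: Assembly, assembly_b: Assembly) -> Assembly:
    """Merge two haplotype assemblies; contig names get 'label|' prefixes."""
    if not assembly_a.contigs or not assembly_b.contigs:
        raise ValueError("both assemblies must be non-empty")
    label_a = assembly_a.source_label or "A"
    label_b = assembly_b.source_label or "B"
    if label_a == label_b:
        raise ValueError(f"source label collision: {label_a!r}")
    contigs = {}
    for label, asm in ((label_a, assembly_a), (label_b, assembly_b)):
        for name, seq in asm.contigs.items():
            contigs[f"{label}{SEPARATOR}{name}"] = seq
    return Assembly(contigs, source_label=f"{label_a}+{label_b}")


def haplotype_of(contig_name: str) -> str:
    """Source label recovered from a diploid contig name."""
    return contig_name.split(SEPARATOR, 1)[0]


def allelic_counts(
    records: list[AlignmentRecord],
    region_a: Feature,
    region_b: Feature,
    library_size: float | None = None,
) -> AllelicCounts:
    """Weighted read counts and percentages over a homologous locus pair.

    ``records`` must come from :func:`pirnakit.mapping.align_allele_specific`
    on the diploid genome; regions are named with the haplotype-prefixed
    contigs and should be restricted to the uniquely mappable span. RPKM
    values are filled in when a library size is supplied.
    """
    from .pirna_stats import rpkm as _rpkm

    def weight_in(region: Feature) -> float:
        return sum(
            r.weight
            for r in records
            if r.target == region.contig and r.start < region.end and r.end > region.start
        )

    count_a = weight_in(region_a)
    count_b = weight_in(region_b)
    rpkm_a = rpkm_b = float("nan")
    if library_size:
        rpkm_a = _rpkm(count_a, region_a.length, library_size)
        rpkm_b = _rpkm(count_b, region_b.length, library_size)
    return AllelicCounts(
        locus_id=f"{region_a.id}/{region_b.id}",
        count_allele_a=count_a,
        count_allele_b=count_b,
        rpkm_a=rpkm_a,
        rpkm_b=rpkm_b,
        defined=(count_a + count_b) > 0,
    )


def informative_fraction(n_retained: float, n_input: float) -> float:
    """Fraction of reads assignable to an allele (divergence-density proxy).

    Reported alongside the percentages because an observed allelic share
    conflates expression share with local variant density.
    """
    return n_retained / n_input if n_input > 0 else float("nan")
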