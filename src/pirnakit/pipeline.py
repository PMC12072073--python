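"""End-to-end pipeline driver over simulated or user-supplied data.

Stages run in dependency order (simulate -> preprocess -> map ->
{stats, cluster}; allelic and chip branch off the simulated inputs);
every run writes a JSON manifest with the tool version, the configuration
snapshot, the seed, output-file digests and per-stage record counts, and a
re-run with identical inputs reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import __version__
from .allelic import allelic_counts, build_diploid
from .chip_enrich import (
    binned_counts,
    binned_coverage,
    compare_enrichment,
    enriched_regions,
    region_means,
    rpgc_normalize,
    subtract_input,
    total_fragment_bases,
)
from .cluster_profile import (
    call_clusters,
    extract_locus,
    homologous_window,
    pairwise_locus_diff,
    stranded_coverage,
)
from .io_formats import (
    Feature,
    read_alignments,
    read_fasta,
    write_bedgraph,
    write_fasta,
    write_features,
    write_sam,
)
from .mapping import align_all, align_allele_specific, filter_unique_best_stratum
from .pirna_stats import (
    count_feature_reads,
    nucleotide_bias,
    pingpong_signature,
    rpkm,
    split_orientation,
)
from .preprocess import (
    collapse_reads,
    filter_by_length,
    read_small_rna,
    subtract_ncrna,
    write_reads_fasta,
)
from .synthetic import (
    SimulationConfig,
    generate_genome_pair,
    simulate_chip_library,
    simulate_hybrid_library,
    simulate_pirna_library,
    synthetic_contaminants,
)

__all__ = ["STAGES", "PipelineError", "run_pipeline"]

log = logging.getLogger("pirnakit")

STAGES = ["simulate", "preprocess", "map", "stats", "cluster", "allelic", "chip"]

_REQUIRES = {
    "preprocess": ["pirna_reads.fastq"],
    "map": ["pirna_kept.fasta", "genome_a.fasta"],
    "stats": ["unique.sam", "annotations_a.gff3"],
    "cluster": ["unique.sam", "genome_a.fasta", "genome_b.fasta"],
    "allelic": ["hybrid_reads.fastq", "genome_a.fasta", "genome_b.fasta", "regions.bed"],
    "chip": ["chip_treat.sam", "chip_naive.sam", "chip_input.sam", "genome_a.fasta"],
}

_PRODUCED_BY = {
    "pirna_reads.fastq": "simulate",
    "genome_a.fasta": "simulate",
    "genome_b.fasta": "simulate",
    "annotations_a.gff3": "simulate",
    "regions.bed": "simulate",
    "hybrid_reads.fastq": "simulate",
    "chip_treat.sam": "simulate",
    "chip_naive.sam": "simulate",
    "chip_input.sam": "simulate",
    "pirna_kept.fasta": "preprocess",
    "unique.sam": "map",
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_fastq(reads, path: Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def _stage_simulate(out: Path, cfg: SimulationConfig, seeds, counts) -> None:
    asm_a, asm_b, annotations, truth = generate_genome_pair(cfg)
    write_fasta(asm_a, out / "genome_a.fasta")
    write_fasta(asm_b, out / "genome_b.fasta")
    write_features(annotations["strainA"], out / "annotations_a.gff3")
    write_features(annotations["strainB"], out / "annotations_b.gff3")
    with open(out / "truth_variants.tsv", "w") as fh:
        fh.write("type\tpos_a\tpos_b\tdetail\n")
        for pa, pb, ba, bb in truth.snps:
            fh.write(f"snp\t{pa}\t{pb}\t{ba}>{bb}\n")
        for pa, pb, L, side in truth.indels:
            fh.write(f"indel\t{pa}\t{pb}\tlen={L};in={side}\n")
    # homologous cluster pair as a BED for the allelic stage
    with open(out / "regions.bed", "w") as fh:
        ca, cb = truth.cluster_a, truth.cluster_b
        fh.write(f"{asm_a.source_label}|{ca.contig}\t{ca.start}\t{ca.end}\tcluster_A\t.\t+\n")
        fh.write(f"{asm_b.source_label}|{cb.contig}\t{cb.start}\t{cb.end}\tcluster_B\t.\t+\n")
    reads, pir_truth = simulate_pirna_library(
        asm_a, truth.cluster_a, cfg.pirna, seed=int(seeds[0])
    )
    _write_fastq(reads, out / "pirna_reads.fastq")
    with open(out / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\torigin\tcontig\tstrand\tfive_prime\tlength\tpartner\tcontaminant\tbackground\n")
        for lab in pir_truth.read_labels.values():
            fh.write(
                f"{lab.read_id}\t{lab.origin}\t{lab.contig}\t{lab.strand}\t{lab.five_prime}"
                f"\t{lab.length}\t{int(lab.is_pingpong_partner)}\t{int(lab.is_contaminant)}"
                f"\t{int(lab.is_background)}\n"
            )
    hyb_reads, _ = simulate_hybrid_library(
        asm_a, asm_b, truth.cluster_a, truth.cluster_b, cfg.hybrid, cfg.pirna, seed=int(seeds[1])
    )
    _write_fastq(hyb_reads, out / "hybrid_reads.fastq")
    treat, input_ = simulate_chip_library(asm_a, [truth.cluster_a], cfg.chip, seed=int(seeds[2]))
    naive_cfg = type(cfg.chip)(
        enrichment_fold=1.0,
        fragment_length=cfg.chip.fragment_length,
        n_fragments=cfg.chip.n_fragments,
    )
    naive, _ = simulate_chip_library(asm_a, [], naive_cfg, seed=int(seeds[3]))
    write_sam(treat, asm_a, out / "chip_treat.sam")
    write_sam(naive, asm_a, out / "chip_naive.sam")
    write_sam(input_, asm_a, out / "chip_input.sam")
    counts["simulate"] = {
        "pirna_reads": len(reads),
        "hybrid_reads": len(hyb_reads),
        "chip_fragments": len(treat) + len(naive) + len(input_),
    }


def _stage_preprocess(out: Path, cfg: SimulationConfig, counts) -> None:
    raw = read_small_rna(out / "pirna_reads.fastq")
    collapsed = collapse_reads(raw)
    sized = filter_by_length(collapsed, 23, 29)
    kept = subtract_ncrna(sized, synthetic_contaminants())
    write_reads_fasta(kept, out / "pirna_kept.fasta")
    n_in = sum(r.count for r in collapsed)
    n_sized = sum(r.count for r in sized)
    n_kept = sum(r.count for r in kept)
    with open(out / "preprocess_summary.tsv", "w") as fh:
        fh.write("step\treads\n")
        fh.write(f"input\t{n_in}\nlength_23_29\t{n_sized}\nncrna_subtracted\t{n_kept}\n")
    counts["preprocess"] = {"input": n_in, "sized": n_sized, "kept": n_kept}


def _read_kept(out: Path):
    reads = read_small_rna(out / "pirna_kept.fasta", fmt="fasta")
    for r in reads:  # ids carry the collapsed multiplicity as _xN
        if "_x" in r.id:
            r.id, _, mult = r.id.rpartition("_x")
            r.count = int(mult)
    return reads


def _stage_map(out: Path, cfg: SimulationConfig, counts, max_mismatch: int = 3) -> None:
    genome = read_fasta(out / "genome_a.fasta", source_label="strainA")
    reads = _read_kept(out)
    records = align_all(reads, genome, max_mismatch=max_mismatch)
    unique = filter_unique_best_stratum(records)
    write_sam(unique, genome, out / "unique.sam")
    counts["map"] = {
        "reads": len(reads),
        "placements": len(records),
        "unique": len(unique),
    }


def _load_unique(out: Path):
    return list(read_alignments(out / "unique.sam", "sam"))


def _stage_stats(out: Path, cfg: SimulationConfig, counts) -> None:
    from .io_formats import read_features

    records = _load_unique(out)
    features = read_features(out / "annotations_a.gff3", "gff3")
    clusters = [f for f in features if f.kind == "cluster"]
    lib_size = sum(r.weight for r in records)
    with open(out / "pirna_stats.tsv", "w") as fh:
        fh.write("locus\tn_sense\tn_antisense\tfrac_1U_sense\tfrac_1U_antisense\tfrac_10A_sense\tz10\n")
        for cl in clusters:
            in_cl = [r for r in records if r.target == cl.contig and r.start < cl.end and r.end > cl.start]
            split = split_orientation(in_cl, cl)
            bias_s = nucleotide_bias(split.sense) if split.sense else None
            bias_a = nucleotide_bias(split.antisense) if split.antisense else None
            pp = pingpong_signature(in_cl)
            fh.write(
                f"{cl.id}\t{split.n_sense:g}\t{split.n_antisense:g}"
                f"\t{bias_s.frac_1U if bias_s else float('nan'):.4f}"
                f"\t{bias_a.frac_1U if bias_a else float('nan'):.4f}"
                f"\t{bias_s.frac_10A if bias_s else float('nan'):.4f}"
                f"\t{pp.z10:.4f}\n"
            )
    gene_feats = [f for f in features if f.kind in ("gene", "exon", "transcript")]
    cts, unassigned, ambiguous = count_feature_reads(records, gene_feats)
    genes = {f.id: f for f in features if f.kind == "gene"}
    with open(out / "expression.tsv", "w") as fh:
        fh.write("feature\tcount\trpkm\n")
        for fid, c in sorted(cts.items()):
            if fid in genes and lib_size > 0:
                fh.write(f"{fid}\t{c:g}\t{rpkm(c, genes[fid].length, lib_size):.4f}\n")
    counts["stats"] = {"records": len(records), "unassigned": unassigned, "ambiguous": ambiguous}


def _stage_cluster(out: Path, cfg: SimulationConfig, counts) -> None:
    genome_a = read_fasta(out / "genome_a.fasta", source_label="strainA")
    genome_b = read_fasta(out / "genome_b.fasta", source_label="strainB")
    records = _load_unique(out)
    cov = stranded_coverage(records, genome_a)
    regions = []
    with open(out / "clusters.bed", "w") as fh:
        for contig, tracks in cov.items():
            write_bedgraph(tracks["+"], out / f"coverage_{contig}_plus.bedgraph")
            write_bedgraph(tracks["-"], out / f"coverage_{contig}_minus.bedgraph")
            for reg in call_clusters(tracks["+"], tracks["-"], records):
                regions.append(reg)
                fh.write(
                    f"{reg.contig}\t{reg.start}\t{reg.end}\tcluster\t{int(reg.dual_strand)}\t.\n"
                )
    with open(out / "locus_diff.tsv", "w") as fh:
        fh.write("region\ttype\tpos_a\tpos_b\tlength\tdetail\n")
        for reg in regions:
            loc_a, sa, _, _ = extract_locus(genome_a, reg)
            window = homologous_window(loc_a, genome_b.contigs[reg.contig])
            if window is None:
                continue
            loc_b = genome_b.contigs[reg.contig][window[0] : window[1]]
            diff = pairwise_locus_diff(loc_a, loc_b)
            for pa, pb, ba, bb in diff.snps:
                fh.write(f"{reg.contig}:{reg.start}-{reg.end}\tsnp\t{pa}\t{pb}\t1\t{ba}>{bb}\n")
            for ind in diff.indels:
                kind = "gap" if ind.length >= diff.gap_min else "indel"
                fh.write(
                    f"{reg.contig}:{reg.start}-{reg.end}\t{kind}\t{ind.pos_a}\t{ind.pos_b}"
                    f"\t{ind.length}\tin={ind.inserted_in}\n"
                )
    counts["cluster"] = {"clusters": len(regions)}


def _stage_allelic(out: Path, cfg: SimulationConfig, counts) -> None:
    from .io_formats import read_bed

    genome_a = read_fasta(out / "genome_a.fasta", source_label="strainA")
    genome_b = read_fasta(out / "genome_b.fasta", source_label="strainB")
    diploid = build_diploid(genome_a, genome_b)
    reads = collapse_reads(read_small_rna(out / "hybrid_reads.fastq"))
    records = align_allele_specific(reads, diploid)
    regions = read_bed(out / "regions.bed")
    region_a = next(r for r in regions if r.contig.startswith("strainA"))
    region_b = next(r for r in regions if r.contig.startswith("strainB"))
    ac = allelic_counts(records, region_a, region_b, library_size=sum(r.weight for r in records))
    with open(out / "allelic.tsv", "w") as fh:
        fh.write("locus\tcount_a\tcount_b\tpct_a\tpct_b\trpkm_a\trpkm_b\n")
        fh.write(
            f"{ac.locus_id}\t{ac.count_allele_a:g}\t{ac.count_allele_b:g}"
            f"\t{ac.pct_a:.3f}\t{ac.pct_b:.3f}\t{ac.rpkm_a:.3f}\t{ac.rpkm_b:.3f}\n"
        )
    counts["allelic"] = {
        "input_reads": sum(r.count for r in reads),
        "retained": len(records),
    }


def _stage_chip(out: Path, cfg: SimulationConfig, counts) -> None:
    genome = read_fasta(out / "genome_a.fasta", source_label="strainA")
    treat = list(read_alignments(out / "chip_treat.sam"))
    naive = list(read_alignments(out / "chip_naive.sam"))
    input_ = list(read_alignments(out / "chip_input.sam"))
    egs = genome.non_n_length()
    flen = cfg.chip.fragment_length
    tracks = {}
    for name, recs in (("treat", treat), ("naive", naive), ("input", input_)):
        raw = binned_coverage(recs, genome, bin_size=10, extend=flen)
        tfb = total_fragment_bases(raw)
        tracks[name] = {c: rpgc_normalize(t, egs, tfb) for c, t in raw.items()}
    contig = next(iter(genome.contigs))
    diff_treat = subtract_input(tracks["treat"][contig], tracks["input"][contig])
    diff_naive = subtract_input(tracks["naive"][contig], tracks["input"][contig])
    write_bedgraph(diff_treat, out / "chip_treat_minus_input.bedgraph")
    t_counts = binned_counts(treat, genome, 10)[contig]
    i_counts = binned_counts(input_, genome, 10)[contig]
    regions = enriched_regions(t_counts, i_counts)
    with open(out / "enriched_regions.bed", "w") as fh:
        for reg in regions:
            fh.write(f"{reg.contig}\t{reg.start}\t{reg.end}\tenriched\t{reg.p_adj:.3g}\t.\n")
    with open(out / "chip_comparison.tsv", "w") as fh:
        fh.write("n_regions\tU\tp_value\tmethod\n")
        if len(regions) >= 3:
            cmp_ = compare_enrichment(
                region_means(diff_treat, regions), region_means(diff_naive, regions)
            )
            fh.write(f"{len(regions)}\t{cmp_.u_statistic:g}\t{cmp_.p_value:.4g}\t{cmp_.method}\n")
        else:
            fh.write(f"{len(regions)}\tNA\tNA\ttoo-few-regions\n")
    counts["chip"] = {"fragments": len(treat) + len(naive) + len(input_), "enriched_regions": len(regions)}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "map": _stage_map,
    "stats": _stage_stats,
    "cluster": _stage_cluster,
    "allelic": _stage_allelic,
    "chip": _stage_chip,
}


def run_pipeline(
    config: SimulationConfig | dict | str | Path | None = None,
    out: str | Path = "pirnakit_out",
    stages: list[str] | None = None,
    seed: int = 0,
    dry_run: bool = False,
    max_mismatch: int = 3,
) -> Path:
    """Execute the analysis graph on simulated data and write a manifest.

    ``stages`` defaults to all stages in dependency order; asking for a
    stage whose upstream products are missing raises a
    :class:`PipelineError` naming the stage to run first.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    elif isinstance(config, (str, Path)):
        config = SimulationConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    config.seed = seed  # the pipeline seed governs all stage randomness
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in (stages or STAGES)]
    out = Path(out)
    if dry_run:
        for s in stages:
            print(f"would run: {s}", file=sys.stderr)
        return out
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    counts: dict[str, dict] = {}
    for stage in stages:
        for req in _REQUIRES.get(stage, []):
            if not (out / req).exists():
                raise PipelineError(
                    f"stage {stage!r} needs {req!r}; run stage "
                    f"{_PRODUCED_BY[req]!r} first"
                )
        log.info("running stage %s", stage)
        if stage == "simulate":
            _stage_simulate(out, config, seeds, counts)
        elif stage == "map":
            _stage_map(out, config, counts, max_mismatch=max_mismatch)
        else:
            _STAGE_FN[stage](out, config, counts)
    digests = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool": "pirnakit",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "stages": stages,
        "counts": counts,
        "digests": digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
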