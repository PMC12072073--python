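import numpy as np
import pytest

from pirnakit.cluster_profile import (
    call_clusters,
    extract_locus,
    homologous_window,
    pairwise_locus_diff,
    stranded_coverage,
)
from pirnakit.io_formats import AlignmentRecord, Assembly

from conftest import random_assembly


def rec(read_id, start, strand, length=26, weight=1.0, target="chr1"):
    return AlignmentRecord(read_id, target, start, strand, length, weight=weight)


class TestStrandedCoverage:
    def test_single_read_increments_its_interval(self):
        asm = random_assembly(1, 400)
        cov = stranded_coverage([rec("r", 100, "+")], asm)["chr1"]
        assert cov["+"].values[100:126].sum() == 26
        assert cov["+"].values.sum() == 26
        assert cov["-"].values.sum() == 0

    def test_collapsed_weight(self):
        asm = random_assembly(2, 400)
        cov = stranded_coverage([rec("r", 50, "-", weight=2.0)], asm)["chr1"]
        assert cov["-"].values[60] == 2.0

    def test_out_of_bounds_record_rejected(self):
        asm = random_assembly(3, 100)
        with pytest.raises(ValueError, match="contig end"):
            stranded_coverage([rec("r", 90, "+")], asm)

    def test_multimapper_fractional_weighting(self):
        asm = random_assembly(4, 400)
        r = rec("r", 10, "+")
        r.n_best = 4
        cov = stranded_coverage([r], asm, multimapper_weighting=True)["chr1"]
        assert cov["+"].values[10] == 0.25


class TestCallClusters:
    def _tracks_and_records(self, asm, positions, strands, weight=1.0):
        records = [
            rec(f"r{i}", p, s, weight=weight) for i, (p, s) in enumerate(zip(positions, strands))
        ]
        cov = stranded_coverage(records, asm)["chr1"]
        return cov["+"], cov["-"], records

    def test_contiguous_tiling_gives_one_region(self):
        asm = random_assembly(5, 6000)
        positions = list(range(10, 4985, 20))
        plus, minus, records = self._tracks_and_records(
            asm, positions, ["+" if i % 2 else "-" for i in range(len(positions))]
        )
        regions = call_clusters(plus, minus, records, min_reads=10, max_gap=1000)
        assert len(regions) == 1
        assert regions[0].start == 10 and regions[0].end == pytest.approx(5000, abs=30)

    def test_islands_beyond_max_gap_split(self):
        asm = random_assembly(6, 9000)
        positions = list(range(0, 1000, 30)) + list(range(3200, 4200, 30))
        plus, minus, records = self._tracks_and_records(
            asm, positions, ["+"] * len(positions)
        )
        regions = call_clusters(plus, minus, records, min_reads=5, max_gap=1000)
        assert len(regions) == 2

    def test_min_reads_floor_drops_sparse_regions(self):
        asm = random_assembly(7, 2000)
        plus, minus, records = self._tracks_and_records(asm, [100, 150], ["+", "+"])
        assert call_clusters(plus, minus, records, min_reads=100) == []

    def test_dual_strand_flag_threshold(self):
        asm = random_assembly(8, 2000)
        positions = [100] * 18 + [200] * 2
        strands = ["+"] * 18 + ["-"] * 2
        plus, minus, records = self._tracks_and_records(asm, positions, strands)
        regions = call_clusters(plus, minus, records, min_reads=5, dual_ratio_threshold=0.1)
        assert regions[0].dual_strand  # 2/18 > 0.1
        regions = call_clusters(plus, minus, records, min_reads=5, dual_ratio_threshold=0.2)
        assert not regions[0].dual_strand

    def test_boundaries_near_truth_on_simulated_cluster(self, genome_pair, small_config):
        from pirnakit.synthetic import simulate_pirna_library, records_from_truth

        asm_a, _, _, truth = genome_pair
        cfg = small_config.pirna
        reads, rt = simulate_pirna_library(asm_a, truth.cluster_a, cfg, seed=3)
        records = records_from_truth(rt, reads)
        cov = stranded_coverage(records, asm_a)["contig_1"]
        regions = call_clusters(cov["+"], cov["-"], records, min_reads=100, max_gap=1000)
        assert len(regions) == 1
        assert abs(regions[0].start - truth.cluster_a.start) <= 1000
        assert abs(regions[0].end - truth.cluster_a.end) <= 1000
        assert regions[0].dual_strand


class TestExtractLocus:
    def test_interior_region(self):
        asm = random_assembly(9, 100_000)
        from pirnakit.cluster_profile import ClusterRegion

        reg = ClusterRegion("chr1", 15_000, 20_000, 1, 1, True)
        seq, start, end, truncated = extract_locus(asm, reg, flank=10_000)
        assert (start, end, truncated) == (5_000, 30_000, False)
        assert seq == asm.contigs["chr1"][5_000:30_000]

    def test_left_truncation_flagged(self):
        asm = random_assembly(10, 50_000)
        from pirnakit.cluster_profile import ClusterRegion

        reg = ClusterRegion("chr1", 3_000, 5_000, 1, 1, True)
        seq, start, end, truncated = extract_locus(asm, reg, flank=10_000)
        assert start == 0 and truncated

    def test_zero_flank_returns_region(self):
        asm = random_assembly(11, 10_000)
        from pirnakit.cluster_profile import ClusterRegion

        reg = ClusterRegion("chr1", 100, 200, 1, 1, True)
        seq, *_ = extract_locus(asm, reg, flank=0)
        assert seq == asm.contigs["chr1"][100:200]


class TestPairwiseLocusDiff:
    def test_identical_sequences(self):
        seq = random_assembly(12, 5000).contigs["chr1"]
        d = pairwise_locus_diff(seq, seq)
        assert d.snps == [] and d.indels == [] and not d.unalignable

    def test_69bp_deletion_recovered_exactly(self):
        seq = random_assembly(13, 20_000).contigs["chr1"]
        removed = seq[:8_000] + seq[8_069:]
        d = pairwise_locus_diff(seq, removed)
        assert [(i.length, i.inserted_in) for i in d.indels] == [(69, "a")]
        assert d.indels[0].pos_a == 8_000

    def test_te_scale_insertion_reported_as_gap(self):
        seq = random_assembly(14, 30_000).contigs["chr1"]
        te = random_assembly(15, 5_403).contigs["chr1"]
        with_te = seq[:12_000] + te + seq[12_000:]
        d = pairwise_locus_diff(with_te, seq)
        assert [(g.length, g.inserted_in) for g in d.gaps] == [(5_403, "a")]

    def test_symmetry_up_to_role_swap(self, genome_pair):
        """SNPs and unique-context indels swap roles exactly; inside tandem
        satellite arrays only the total indel length is representation-stable."""
        asm_a, asm_b, annotations, _ = genome_pair
        a = asm_a.contigs["contig_1"]
        b = asm_b.contigs["contig_1"]
        d_ab = pairwise_locus_diff(a, b)
        d_ba = pairwise_locus_diff(b, a)
        assert sorted((pb, pa, bb, ba) for pa, pb, ba, bb in d_ab.snps) == sorted(d_ba.snps)
        sats = [f for f in annotations["strainA"] if f.kind == "satellite"]

        def in_sat(pos):
            return any(f.start - 50 <= pos <= f.end + 50 for f in sats)

        swap = {"a": "b", "b": "a"}
        uniq_ab = sorted(
            (i.pos_b, i.pos_a, i.length, swap[i.inserted_in])
            for i in d_ab.indels
            if not in_sat(i.pos_a)
        )
        uniq_ba = sorted(
            (i.pos_a, i.pos_b, i.length, i.inserted_in)
            for i in d_ba.indels
            if not in_sat(i.pos_b)
        )
        assert uniq_ab == uniq_ba
        total = lambda d, side: sum(i.length for i in d.indels if i.inserted_in == side)
        assert total(d_ab, "a") == total(d_ba, "b")
        assert total(d_ab, "b") == total(d_ba, "a")

    def test_planted_variants_recovered_from_generator(self, genome_pair):
        asm_a, asm_b, _, truth = genome_pair
        d = pairwise_locus_diff(asm_a.contigs["contig_1"], asm_b.contigs["contig_1"])
        assert set(truth.snps) <= set(d.snps)
        found = {(i.pos_a, i.pos_b, i.length, i.inserted_in) for i in d.indels}
        for planted in truth.planted_indels:
            assert planted in found
        te_pos, te_len = truth.te
        assert any(i.pos_a == te_pos and i.length == te_len for i in d.indels)

    def test_unrelated_sequences_flagged_unalignable(self):
        a = random_assembly(16, 3000).contigs["chr1"]
        b = random_assembly(17, 3000).contigs["chr1"]
        d = pairwise_locus_diff(a, b)
        assert d.unalignable

    def test_satellite_array_threefold_shorter_in_naive_strain(self, genome_pair):
        from pirnakit.cluster_profile import satellite_array_length

        _, _, ann, _ = genome_pair
        sat_370 = lambda feats: sum(
            f.length for f in feats if f.id == "sat_370_array"
        )
        ratio = sat_370(ann["strainA"]) / sat_370(ann["strainB"])
        assert ratio == pytest.approx(3.0)
        assert satellite_array_length(ann["strainA"]) > satellite_array_length(ann["strainB"])

    def test_homologous_window_locates_segment(self):
        seq = random_assembly(18, 40_000).contigs["chr1"]
        window = homologous_window(seq[10_000:15_000], seq, margin=100)
        assert window is not None
        lo, hi = window
        assert lo <= 10_000 and hi >= 15_000 and hi - lo < 6_000
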