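"""Aligner, best-stratum unique filter, allele-specific mode, mappability.

The brute-force oracle used throughout is an O(L*n) per-position substring
comparison written independently of the numpy/str.find implementation.
"""

import numpy as np
import pytest

from pirnakit.allelic import build_diploid
from pirnakit.io_formats import Assembly, revcomp
from pirnakit.mapping import (
    align_all,
    align_allele_specific,
    compute_mappability,
    filter_unique_best_stratum,
)
from pirnakit.preprocess import SmallRNARead

from conftest import random_assembly


def brute_force_placements(seq: str, asm: Assembly, max_mismatch: int):
    """Every placement of seq on either strand with <= max_mismatch mismatches."""
    out = []
    for name, contig in asm.contigs.items():
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for start in range(len(contig) - len(seq) + 1):
                mm = sum(
                    1
                    for a, b in zip(query, contig[start : start + len(seq)])
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mismatch:
                    out.append((name, start, strand, mm))
    return sorted(out)


class TestAlignAll:
    def test_unique_exact_hit(self):
        asm = random_assembly(1, 400)
        read = SmallRNARead("r", asm.contigs["chr1"][100:126])
        recs = align_all([read], asm, max_mismatch=0)
        assert len(recs) == 1
        assert (recs[0].start, recs[0].strand, recs[0].mismatches, recs[0].n_best) == (100, "+", 0, 1)

    def test_duplicated_sequence_sets_n_best(self):
        core = random_assembly(2, 300).contigs["chr1"]
        asm = Assembly({"c": core + core[50:76] + core[-30:]})
        read = SmallRNARead("r", core[50:76])
        recs = align_all([read], asm, max_mismatch=0)
        assert len(recs) == 2 and all(r.n_best == 2 for r in recs)

    def test_minus_strand_placement(self):
        asm = random_assembly(3, 200)
        read = SmallRNARead("r", revcomp(asm.contigs["chr1"][40:66]))
        recs = align_all([read], asm, max_mismatch=0)
        assert [(r.start, r.strand) for r in recs] == [(40, "-")]
        assert recs[0].five_prime == 65

    def test_mismatch_strata(self):
        """A read hitting once exactly and once with 2 mismatches: stratum 0 unique."""
        core = random_assembly(4, 300).contigs["chr1"]
        exact = core[10:36]
        noisy = list(exact)
        noisy[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[5]]
        noisy[15] = {"A": "G", "C": "T", "G": "A", "T": "C"}[noisy[15]]
        asm = Assembly({"c": core + "".join(noisy) + core[200:230]})
        recs = align_all([SmallRNARead("r", exact)], asm, max_mismatch=3)
        strata = sorted(r.mismatches for r in recs)
        assert strata[0] == 0 and 2 in strata
        best = [r for r in recs if r.mismatches == 0]
        assert len(best) == 1 and best[0].n_best == 1

    def test_read_longer_than_contig_yields_nothing(self):
        asm = Assembly({"c": "ACGTACGT"})
        assert align_all([SmallRNARead("r", "A" * 20)], asm, 0) == []

    def test_n_in_read_never_matches(self):
        asm = Assembly({"c": "ACGTNACGTACGTACGTACGTACGT"})
        read = SmallRNARead("r", asm.contigs["c"][:10])  # contains N
        assert align_all([read], asm, max_mismatch=0) == []
        recs = align_all([read], asm, max_mismatch=1)
        assert recs and recs[0].mismatches == 1

    @pytest.mark.parametrize("max_mismatch", [0, 1, 3])
    def test_agrees_with_brute_force(self, max_mismatch):
        rng = np.random.default_rng(42 + max_mismatch)
        asm = random_assembly(900 + max_mismatch, 800)
        contig = asm.contigs["chr1"]
        reads = []
        for i in range(12):
            start = int(rng.integers(0, 770))
            seq = list(contig[start : start + 24])
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, 24))
                seq[pos] = "ACGT"[int(rng.integers(0, 4))]
            s = "".join(seq)
            reads.append(SmallRNARead(f"r{i}", revcomp(s) if i % 2 else s))
        got = align_all(reads, asm, max_mismatch)
        for read in reads:
            expected = brute_force_placements(read.sequence, asm, max_mismatch)
            mine = sorted(
                (r.target, r.start, r.strand, r.mismatches)
                for r in got
                if r.read_id == read.id
            )
            assert mine == expected


class TestUniqueBestStratum:
    def _mk(self, read_id, mismatches):
        from pirnakit.io_formats import AlignmentRecord

        return [
            AlignmentRecord(read_id, "c", 10 * i, "+", 26, mismatches=m, n_best=1)
            for i, m in enumerate(mismatches)
        ]

    def test_single_exact_kept(self):
        assert len(filter_unique_best_stratum(self._mk("a", [0]))) == 1

    def test_tied_best_discarded(self):
        assert filter_unique_best_stratum(self._mk("a", [0, 0])) == []

    def test_unique_best_among_worse_kept(self):
        out = filter_unique_best_stratum(self._mk("a", [1, 3, 3]))
        assert len(out) == 1 and out[0].mismatches == 1

    def test_output_always_n_best_one(self):
        recs = self._mk("a", [1, 2]) + self._mk("b", [0, 0, 2])
        out = filter_unique_best_stratum(recs)
        assert {r.read_id for r in out} == {"a"}
        assert all(r.n_best == 1 for r in out)


class TestAlleleSpecific:
    def test_snp_spanning_read_assigned_to_true_allele(self):
        base = random_assembly(7, 500).contigs["chr1"]
        alt = base[:250] + ("A" if base[250] != "A" else "C") + base[251:]
        asm_a = Assembly({"chr1": base}, source_label="A")
        asm_b = Assembly({"chr1": alt}, source_label="B")
        dip = build_diploid(asm_a, asm_b)
        read = SmallRNARead("r", alt[240:266])  # spans the diagnostic SNP
        recs = align_allele_specific([read], dip)
        assert len(recs) == 1 and recs[0].target == "B|chr1"

    def test_shared_sequence_discarded(self):
        base = random_assembly(8, 500).contigs["chr1"]
        asm_a = Assembly({"chr1": base}, source_label="A")
        asm_b = Assembly({"chr1": base[:100] + base[100:]}, source_label="B")
        dip = build_diploid(asm_a, asm_b)
        read = SmallRNARead("r", base[10:36])
        assert align_allele_specific([read], dip) == []

    def test_perfect_precision_on_error_free_reads(self, genome_pair):
        from pirnakit.synthetic import simulate_hybrid_library, HybridConfig

        asm_a, asm_b, _, truth = genome_pair
        reads, ht = simulate_hybrid_library(
            asm_a, asm_b, truth.cluster_a, truth.cluster_b,
            HybridConfig(minor_allele_fraction=0.3, n_reads=1500), seed=5,
        )
        dip = build_diploid(asm_a, asm_b)
        recs = align_allele_specific(reads, dip)
        assert recs, "some reads must be allele-informative"
        labels = ht.read_labels
        assert all(
            r.target.split("|")[0] == labels[r.read_id].origin for r in recs
        )


class TestMappability:
    def brute(self, asm: Assembly, k: int):
        """Oracle via C-speed overlapping substring search, no hashing."""

        def count_occurrences(kmer):
            total = 0
            for seq in asm.contigs.values():
                i = seq.find(kmer)
                while i != -1:
                    total += 1
                    i = seq.find(kmer, i + 1)
            return total

        out = {}
        for name, seq in asm.contigs.items():
            out[name] = [
                1 if count_occurrences(seq[i : i + k]) == 1 else 0
                for i in range(len(seq) - k + 1)
            ]
        return out

    def test_repeated_kmers_marked_zero(self):
        asm = Assembly({"c": "ACGTACGT"})
        track = compute_mappability(asm, 5)["c"]
        # ACGTA occurs once; CGTAC, GTACG, TACGT also once -> all unique here
        assert track.values.tolist() == self.brute(asm, 5)["c"]

    def test_tandem_duplication_unmappable(self):
        block = random_assembly(10, 100).contigs["chr1"]
        asm = Assembly({"c": block + block + random_assembly(11, 50).contigs["chr1"]})
        track = compute_mappability(asm, 25)["c"]
        assert track.values[:75].sum() == 0  # k-mers inside the first copy repeat
        assert track.values.tolist() == self.brute(asm, 25)["c"]

    def test_random_long_kmers_all_unique(self):
        asm = random_assembly(12, 2000)
        track = compute_mappability(asm, 25)["chr1"]
        assert track.unique_fraction == 1.0

    def test_invalid_k_rejected(self):
        asm = Assembly({"c": "ACGTACGT"})
        with pytest.raises(ValueError):
            compute_mappability(asm, 0)
        with pytest.raises(ValueError):
            compute_mappability(asm, 100)
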