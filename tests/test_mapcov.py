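import numpy as np
import pytest
from Bio import Align

from polyptome.errors import EstimationError, InputError
from polyptome.mapcov import (
    BlockAlignment,
    align_read_to_contig,
    assign_best_hits,
    build_pileup,
    contig_mean_coverage,
    coverage_summary,
    estimate_genome_size,
    is_valid_alignment,
    modal_coverage,
    read_alignments_tsv,
    read_sam,
    write_alignments_tsv,
)
from polyptome.seqio import Contig, reverse_complement
from polyptome.simulate import SimConfig, simulate_genomic_reads, true_alignments


def simple_aln(matches, aligned, gaps=0, contig="c", blocks=None, strand="+"):
    if blocks is None:
        blocks = ((0, 0, aligned),)
    return BlockAlignment(
        read_id="r", contig_id=contig, strand=strand, blocks=blocks,
        matches=matches, aligned_bases=aligned, gaps=gaps,
    )


class TestValidity:
    def test_published_88bp_illustration(self):
        # 88 bp read, 35 aligned: 35/88 = 0.398 < 0.40 -> invalid even at
        # 34/35 matches (the identity floor alone would pass)
        aln = simple_aln(34, 35)
        assert not is_valid_alignment(aln, read_length=88)

    def test_forty_percent_boundary_is_inclusive(self):
        assert is_valid_alignment(simple_aln(39, 40), read_length=100)

    def test_identity_boundary(self):
        assert not is_valid_alignment(simple_aln(95, 100), read_length=100)
        assert is_valid_alignment(simple_aln(96, 100), read_length=100)

    def test_raising_thresholds_never_admits_a_rejected_alignment(self, rng):
        for _ in range(200):
            aligned = int(rng.integers(1, 101))
            matches = int(rng.integers(0, aligned + 1))
            aln = simple_aln(matches, aligned)
            grid = [0.2, 0.4, 0.6, 0.9, 0.96, 1.0]
            for lo, hi in zip(grid, grid[1:]):
                if not is_valid_alignment(aln, 100, min_frac=lo):
                    assert not is_valid_alignment(aln, 100, min_frac=hi)
                if not is_valid_alignment(aln, 100, min_ident=lo):
                    assert not is_valid_alignment(aln, 100, min_ident=hi)


class TestAligner:
    def test_exact_substring_aligns_full_length(self, random_contig):
        contig = random_contig(500)
        read = contig.seq[100:200]
        aln = align_read_to_contig(read, contig)
        assert aln is not None
        assert aln.blocks == ((0, 100, 100),)
        assert aln.matches == aln.aligned_bases == 100
        assert aln.identity == 1.0 and aln.strand == "+"

    def test_minus_strand_read_is_found(self, random_contig):
        contig = random_contig(500)
        read = reverse_complement(contig.seq[100:200])
        aln = align_read_to_contig(read, contig)
        assert aln is not None and aln.strand == "-"
        assert aln.aligned_bases == 100 and aln.matches == 100

    def test_two_mismatches_counted(self, random_contig):
        contig = random_contig(400)
        read = list(contig.seq[50:150])
        for pos in (30, 60):
            read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
        aln = align_read_to_contig("".join(read), contig)
        assert aln.matches == 98
        assert aln.aligned_bases == 100

    def test_no_shared_kmer_returns_none(self):
        contig = Contig("c", "A" * 300)
        assert align_read_to_contig("C" * 50, contig) is None

    @pytest.mark.parametrize("trial", range(8))
    def test_score_matches_smith_waterman_oracle(self, rng, trial, random_contig):
        """Alignment score equals Biopython's exhaustive local DP."""
        contig = random_contig(200, f"c{trial}")
        start = int(rng.integers(0, 80))
        read = list(contig.seq[start : start + 90])
        # sprinkle mismatches and a small indel
        for pos in rng.integers(5, 85, size=3):
            read[pos] = "ACGT"[int(rng.integers(0, 4))]
        if trial % 2:
            del read[40:42]
        read = "".join(read)
        aln = align_read_to_contig(read, contig)
        assert aln is not None
        oracle = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        assert aln.score == oracle.score(contig.seq, read)


class TestPileup:
    def test_single_exact_read(self, random_contig):
        contig = random_contig(200)
        aln = BlockAlignment("r1", contig.id, "+", ((0, 50, 100),), 100, 100, 0)
        pile = build_pileup([aln], [contig], {"r1": contig.seq[50:150]})
        depth = pile.depth(contig.id)
        assert depth[50:150].sum() == 100
        assert depth[:50].sum() == 0 and depth[150:].sum() == 0

    def test_overlapping_reads_add(self, random_contig):
        contig = random_contig(200)
        reads = {"a": contig.seq[0:100], "b": contig.seq[50:150]}
        alns = [
            BlockAlignment("a", contig.id, "+", ((0, 0, 100),), 100, 100, 0),
            BlockAlignment("b", contig.id, "+", ((0, 50, 100),), 100, 100, 0),
        ]
        pile = build_pileup(alns, [contig], reads)
        assert (pile.depth(contig.id)[50:100] == 2).all()

    def test_minus_strand_contributes_complemented_bases(self, random_contig):
        contig = random_contig(200)
        read = reverse_complement(contig.seq[20:120])
        aln = BlockAlignment("r", contig.id, "-", ((0, 20, 100),), 100, 100, 0)
        pile = build_pileup([aln], [contig], {"r": read})
        # every contributed base must equal the reference -> depth == ref count
        from polyptome.seqio import encode_bases

        codes = encode_bases(contig.seq)
        counts = pile.counts[contig.id]
        for pos in range(20, 120):
            assert counts[codes[pos], pos] == 1

    def test_unknown_contig_rejected(self, random_contig):
        contig = random_contig(200)
        aln = BlockAlignment("r", "nope", "+", ((0, 0, 50),), 50, 50, 0)
        with pytest.raises(InputError):
            build_pileup([aln], [contig], {"r": "A" * 50})

    def test_depth_matches_interval_stabbing_oracle(self):
        """Simulated error-free data: pileup depth equals a direct
        per-read interval count at every position."""
        cfg = SimConfig(n_contigs=10, coverage=10, error_rate=0.0,
                        snv_rate=0.0, indel_rate=0.0, seed=21)
        from polyptome.simulate import simulate_diploid_transcriptome

        contigs, haps, _ = simulate_diploid_transcriptome(cfg)
        reads, origins = simulate_genomic_reads(haps, cfg)
        read_map = {r.id: r for r in reads}
        alns = list(true_alignments(origins, haps, cfg.read_length))
        pile = build_pileup(alns, contigs, read_map)
        for contig in contigs:
            oracle = np.zeros(contig.length, dtype=int)
            for org in origins:
                if org.contig == contig.id:
                    oracle[org.start : org.start + cfg.read_length] += 1
            assert (pile.depth(contig.id) == oracle).all()

    def test_indel_openings_tallied_at_left_flank(self, random_contig):
        contig = random_contig(200)
        # read skips contig positions 60..62 (3 bp deletion)
        read = contig.seq[20:60] + contig.seq[63:123]
        aln = BlockAlignment(
            "r", contig.id, "+", ((0, 20, 40), (40, 63, 60)), 100, 100, 1
        )
        pile = build_pileup([aln], [contig], {"r": read})
        assert pile.indels[contig.id][59] == {("D", 3): 1}


class TestCoverage:
    def test_mean_coverage_arithmetic(self, random_contig):
        contig = random_contig(1000)
        alns = [
            BlockAlignment(f"r{i}", contig.id, "+", ((0, 0, 100),), 100, 100, 0)
            for i in range(10)
        ]
        assert contig_mean_coverage(alns, contig) == 1.0

    def test_no_reads_gives_zero(self, random_contig):
        assert contig_mean_coverage([], random_contig(500)) == 0.0

    def test_best_hit_assignment_prefers_score_then_first(self, random_contig):
        a = simple_aln(100, 100, contig="c1")
        b = simple_aln(90, 100, contig="c2")
        best = assign_best_hits({"r": [b, a]})
        assert best[0].contig_id == "c1"
        tie = assign_best_hits({"r": [simple_aln(90, 100, contig="c2"),
                                      simple_aln(90, 100, contig="c1")]})
        assert tie[0].contig_id == "c2"  # first listed wins ties

    def test_gapped_alignments_excluded_from_coverage(self):
        gapped = BlockAlignment(
            "r", "c", "+", ((0, 0, 50), (50, 60, 50)), 100, 100, 1
        )
        assert assign_best_hits({"r": [gapped]}) == []

    def test_modal_coverage_rounds_then_counts(self):
        assert modal_coverage([23.6, 24.2, 24.4, 7.1]) == 24

    def test_modal_coverage_tie_breaks_low(self):
        assert modal_coverage([10.0, 20.0]) == 10

    def test_modal_coverage_excludes_zero_and_errors_on_all_zero(self):
        assert modal_coverage([0.0, 5.0, 5.2]) == 5
        with pytest.raises(EstimationError):
            modal_coverage([0.0, 0.0])

    def test_genome_size_worked_example(self):
        # 10,100 Mb of genomic reads at modal coverage 24 -> 421 Mb
        mb = estimate_genome_size(10_100, 24)
        assert round(mb) == 421

    def test_genome_size_identity_case(self):
        assert estimate_genome_size(24, 24) == 1.0

    def test_genome_size_rejects_zero_depth(self):
        with pytest.raises(EstimationError):
            estimate_genome_size(1000, 0)

    def test_estimate_is_scale_equivariant(self, random_contig):
        """Doubling every read leaves the genome-size estimate fixed."""
        contigs = [random_contig(1000, f"c{i}") for i in range(20)]
        by_read = {}
        n = 0
        for c in contigs:
            for i in range(20):  # 20 x 100bp on 1000bp -> 2x coverage... scaled
                aln = BlockAlignment(
                    f"r{n}", c.id, "+", ((0, 0, 100),), 100, 100, 0
                )
                by_read[f"r{n}"] = [aln]
                n += 1
        total = n * 100
        s1 = coverage_summary(by_read, contigs, total)
        doubled = dict(by_read)
        for c in contigs:
            for i in range(20):
                aln = BlockAlignment(
                    f"d{n}", c.id, "+", ((0, 0, 100),), 100, 100, 0
                )
                doubled[f"d{n}"] = [aln]
                n += 1
        s2 = coverage_summary(doubled, contigs, 2 * total)
        assert s2.modal == 2 * s1.modal
        assert s2.genome_size == s1.genome_size


class TestAlignmentIO:
    def test_tsv_round_trip(self, tmp_path):
        alns = [
            BlockAlignment("r1", "c1", "+", ((0, 5, 50),), 49, 50, 0),
            BlockAlignment("r2", "c2", "-", ((0, 0, 30), (35, 40, 30)), 58, 60, 1),
        ]
        p = tmp_path / "aln.tsv"
        write_alignments_tsv(alns, p)
        assert read_alignments_tsv(p) == alns

    def test_sam_blocks_and_strand(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:300\n"
            "r1\t0\tc1\t11\t60\t40M2D60M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:3\n"
            "r2\t16\tc1\t21\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNM:i:0\n"
        )
        alns = read_sam(sam)
        assert alns[0].blocks == ((0, 10, 40), (40, 52, 60))
        assert alns[0].gaps == 1
        assert alns[0].matches == 99  # NM 3 includes the 2 deleted bases
        assert alns[1].strand == "-"
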