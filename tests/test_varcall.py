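import itertools

import pytest

from polyptome.errors import InputError, ParameterError
from polyptome.mapcov import BlockAlignment, Pileup, build_pileup
from polyptome.seqio import Contig
from polyptome.simulate import SimConfig
from polyptome.varcall import (
    VariantCall,
    call_variants,
    classify_substitution,
    round_half_up,
    snv_density,
    summarize_variants,
    write_vcf,
)


def pileup_with(contig, column_counts):
    """Build a pileup with explicit per-position base counts."""
    pile = Pileup([contig])
    for pos, counts in column_counts.items():
        for base, n in counts.items():
            row = "ACGT".index(base)
            pile.counts[contig.id][row, pos] = n
    return pile


@pytest.fixture
def contig():
    return Contig("c", "A" * 50)


class TestCallVariants:
    def test_threshold_arithmetic_calls_40_percent_site(self, contig):
        pile = pileup_with(contig, {10: {"A": 6, "G": 4}})
        calls = call_variants(pile, [contig])
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alt, c.depth) == (10, "A", "G", 10)
        assert c.alt_fraction == pytest.approx(0.4)
        assert c.var_class == "transition"

    def test_coverage_floor_blocks_low_depth_site(self, contig):
        pile = pileup_with(contig, {10: {"A": 5, "G": 4}})  # depth 9, frac 0.44
        assert call_variants(pile, [contig]) == []

    def test_fraction_boundary_is_inclusive(self, contig):
        pile = pileup_with(contig, {5: {"A": 13, "G": 7}})  # 7/20 = 0.35
        assert len(call_variants(pile, [contig])) == 1
        pile = pileup_with(contig, {5: {"A": 14, "G": 6}})  # 6/20 = 0.30
        assert call_variants(pile, [contig]) == []

    def test_raising_min_frac_only_shrinks_the_call_set(self, contig):
        pile = pileup_with(
            contig,
            {5: {"A": 10, "G": 10}, 15: {"A": 12, "G": 8}, 25: {"A": 15, "G": 5}},
        )
        sets = [
            {(c.pos, c.alt) for c in call_variants(pile, [contig], min_frac=f)}
            for f in (0.25, 0.35, 0.45, 0.55)
        ]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_ref_below_fraction_is_flagged_not_split(self, contig):
        pile = pileup_with(contig, {8: {"A": 2, "G": 18}})  # ref A at 10%
        calls = call_variants(pile, [contig])
        assert len(calls) == 1
        assert calls[0].ref_below_frac

    def test_alt_tie_breaks_lexicographically(self, contig):
        pile = pileup_with(contig, {8: {"A": 10, "C": 5, "G": 5}})
        calls = call_variants(pile, [contig], min_frac=0.25)
        assert calls[0].alt == "C"

    def test_indel_called_from_opening_tallies(self, contig):
        pile = pileup_with(contig, {20: {"A": 20}})
        for _ in range(8):
            pile.add_indel(contig.id, 20, ("D", 2))
        calls = call_variants(pile, [contig])
        assert len(calls) == 1
        c = calls[0]
        assert c.var_class == "indel"
        assert (c.pos, c.ref, c.alt) == (20, "AAA", "A")
        assert c.alt_fraction == pytest.approx(0.4)

    def test_no_calls_on_clean_haploid_data(self):
        """Error-free homozygous simulation yields zero SNVs."""
        from polyptome.pipeline import run_snv_experiment

        cfg = SimConfig(
            n_contigs=20, snv_rate=0.0, indel_rate=0.0, error_rate=0.0,
            coverage=15, seed=31,
        )
        exp = run_snv_experiment(cfg)
        assert exp.calls == []

    def test_unknown_contig_rejected(self, contig):
        pile = pileup_with(contig, {})
        with pytest.raises(InputError):
            call_variants(pile, [contig, Contig("other", "ACGT" * 60)])

    def test_emitted_calls_respect_floors(self, contig, rng):
        pile = Pileup([contig])
        pile.counts[contig.id][:, :] = rng.integers(0, 12, size=(4, 50))
        for c in call_variants(pile, [contig]):
            assert c.depth >= 10
            assert c.alt_fraction >= 0.35 - 1e-9


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", "transition"), ("C", "T", "transition"),
         ("G", "C", "transversion"), ("A", "T", "transversion")],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_exhaustive_enumeration_4_transitions_8_transversions(self):
        outcomes = [
            classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        ]
        assert outcomes.count("transition") == 4
        assert outcomes.count("transversion") == 8

    def test_identical_alleles_rejected(self):
        with pytest.raises(ParameterError):
            classify_substitution("A", "A")


class TestSummary:
    def test_published_density_arithmetic(self):
        # 44.7 Mb of contigs, 55,300 SNVs -> 1 SNV per 808 bp
        assert snv_density(44_700_000, 55_300) == 808

    def test_single_snv_density(self):
        assert snv_density(1000, 1) == 1000

    def test_zero_snvs_density_undefined(self):
        assert snv_density(1000, 0) is None
        assert summarize_variants([], 1000).density_bp is None

    def test_indel_histogram_binning_with_overflow(self):
        calls = [
            VariantCall("c", i, ref, alt, 20, 0.5, "indel")
            for i, (ref, alt) in enumerate(
                [("AT", "A"), ("AC", "A"), ("AGG", "A"),
                 ("A", "ACCCCCCCC"), ("A" + "G" * 9, "A")]
            )
        ]
        s = summarize_variants(calls, 10_000)
        assert s.indel_count == 5
        assert s.indel_size_histogram["1"] == 2
        assert s.indel_size_histogram["2"] == 1
        assert s.indel_size_histogram["8"] == 1
        assert s.indel_size_histogram["8+"] == 1

    def test_class_counts_partition_total(self):
        calls = [
            VariantCall("c", i, r, a, 20, 0.5, classify_substitution(r, a))
            for i, (r, a) in enumerate(
                [("A", "G"), ("G", "A"), ("C", "T"), ("G", "C"), ("C", "G"),
                 ("T", "G"), ("A", "C")]
            )
        ]
        s = summarize_variants(calls, 10_000)
        assert sum(s.snv_class_counts.values()) == s.total_snvs == 7
        assert s.snv_class_counts["A/G"] == 2
        assert s.snv_class_counts["G/C"] == 2
        assert s.transitions == 3 and s.transversions == 4

    def test_round_half_up(self):
        assert round_half_up(81.5) == 82
        assert round_half_up(78.51) == 79
        assert round_half_up(72.98) == 73
        assert round_half_up(0.49) == 0


class TestVcf:
    def test_round_trip_through_independent_reader(self, tmp_path, random_contig):
        pytest.importorskip("cyvcf2")
        import cyvcf2

        contig = random_contig(200, "c1")
        calls = [
            VariantCall("c1", 99, contig.seq[99], "G" if contig.seq[99] != "G" else "A",
                        20, 0.45, "transition"),
            VariantCall("c1", 120, contig.seq[120:123], contig.seq[120],
                        15, 0.40, "indel"),
        ]
        path = tmp_path / "calls.vcf"
        write_vcf(calls, [contig], path)
        records = list(cyvcf2.VCF(str(path)))
        assert [r.POS for r in records] == [100, 121]  # 1-based
        assert records[0].REF == calls[0].ref
        assert records[0].ALT == [calls[0].alt]
        assert records[0].INFO["DP"] == 20
        assert records[1].REF == calls[1].ref and records[1].ALT == [calls[1].alt]

    def test_unsorted_input_rejected(self, tmp_path, random_contig):
        contig = random_contig(200, "c1")
        calls = [
            VariantCall("c1", 50, "A", "G", 20, 0.5, "transition"),
            VariantCall("c1", 10, "A", "G", 20, 0.5, "transition"),
        ]
        with pytest.raises(InputError):
            write_vcf(calls, [contig], tmp_path / "x.vcf")
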