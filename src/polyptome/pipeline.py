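"""End-to-end simulated experiments wiring the modules together.

These drive the package's recovery checks and the CLI demo: simulate a
diploid transcriptome, sequence it, map the reads via the simulator's
recorded provenance (exact truth alignments), call variants, and compare
against the planted truth; or embed a transcriptome in a larger genome
and recover the genome size from modal coverage.

Truth alignments — not the heuristic aligner — carry the reads here on
purpose: the experiments measure the variant caller and the coverage
estimator under known mapping, while the aligner is validated separately
against an exhaustive dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mapcov import (
    build_pileup,
    coverage_summary,
    CoverageSummary,
    is_valid_alignment,
)
from .seqio import Contig
from .simulate import (
    SimConfig,
    TruthTable,
    simulate_diploid_transcriptome,
    simulate_genomic_reads,
    true_alignments,
)
from .varcall import VariantCall, VariantSummary, call_variants, summarize_variants


@dataclass
class SnvExperiment:
    """Outcome of a simulate -> sequence -> pileup -> call experiment."""

    contigs: list[Contig]
    truth: TruthTable
    calls: list[VariantCall]
    summary: VariantSummary
    total_bp: int
    recall: float
    precision: float
    planted_ts_fraction: float
    called_ts_fraction: float

    @property
    def called_density_bp(self) -> int | None:
        return self.summary.density_bp


def run_snv_experiment(
    config: SimConfig,
    min_cov: int = 10,
    min_frac: float = 0.35,
    min_aln_frac: float = 0.40,
    min_aln_ident: float = 0.96,
) -> SnvExperiment:
    """Full SNV-recovery experiment against the planted truth.

    Processes one contig at a time (reads, truth alignments, pileup,
    calls) to keep memory flat; per-contig seeds derive deterministically
    from ``config.seed``.
    """
    contigs, haplotypes, truth = simulate_diploid_transcriptome(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(contigs)) % (2**31)
    all_calls: list[VariantCall] = []
    for contig, sub_seed in zip(contigs, seeds):
        pair = {contig.id: haplotypes[contig.id]}
        sub_config = replace(config, seed=int(sub_seed))
        reads, origins = simulate_genomic_reads(pair, sub_config)
        read_map = {r.id: r for r in reads}
        valid = (
            aln
            for aln in true_alignments(origins, pair, config.read_length)
            if is_valid_alignment(
                aln, config.read_length, min_aln_frac, min_aln_ident
            )
        )
        pile = build_pileup(valid, [contig], read_map)
        all_calls.extend(call_variants(pile, [contig], min_cov, min_frac))

    total_bp = sum(c.length for c in contigs)
    summary = summarize_variants(all_calls, total_bp)

    truth_snvs = {(v.contig, v.pos, v.alt) for v in truth.snvs()}
    called_snvs = {(c.contig, c.pos, c.alt) for c in all_calls if not c.is_indel}
    tp = len(truth_snvs & called_snvs)
    recall = tp / len(truth_snvs) if truth_snvs else float("nan")
    precision = tp / len(called_snvs) if called_snvs else float("nan")

    planted = truth.snvs()
    planted_ts = sum(v.var_class == "transition" for v in planted)
    called_snv_calls = [c for c in all_calls if not c.is_indel]
    called_ts = sum(c.var_class == "transition" for c in called_snv_calls)
    return SnvExperiment(
        contigs=contigs,
        truth=truth,
        calls=all_calls,
        summary=summary,
        total_bp=total_bp,
        recall=recall,
        precision=precision,
        planted_ts_fraction=planted_ts / len(planted) if planted else float("nan"),
        called_ts_fraction=(
            called_ts / len(called_snv_calls) if called_snv_calls else float("nan")
        ),
    )


@dataclass
class GenomeSizeExperiment:
    """Outcome of the modal-coverage genome-size recovery experiment."""

    true_genome_size: int
    transcriptome_bp: int
    total_read_bases: int
    summary: CoverageSummary

    @property
    def estimate(self) -> float:
        return self.summary.genome_size

    @property
    def relative_error(self) -> float:
        return abs(self.estimate - self.true_genome_size) / self.true_genome_size


def run_genome_size_experiment(
    genome_size: int = 5_000_000,
    transcribed_fraction: float = 0.4,
    coverage: float = 20.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
    intergenic_piece: int = 100_000,
) -> GenomeSizeExperiment:
    """Recover a known genome size from modal transcriptome coverage.

    The genome is modelled as transcribed pieces (contigs, sampled from
    the study's length law until they total ``transcribed_fraction`` of
    the genome) plus intergenic pieces.  Reads are sampled uniformly
    across the whole genome; only reads originating on transcribed
    pieces align to the transcriptome.  The estimate is total read bases
    divided by the modal per-contig coverage.
    """
    base = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    target = int(genome_size * transcribed_fraction)
    contig_lengths: list[int] = []
    total = 0
    while total < target:
        L = int(
            np.clip(
                rng.lognormal(base.length_log_mean, base.length_log_sd),
                base.min_contig_len,
                base.max_contig_len,
            )
        )
        contig_lengths.append(L)
        total += L

    from .simulate import _random_seq  # module-internal helper

    pieces: dict[str, str] = {}
    contigs: list[Contig] = []
    for i, L in enumerate(contig_lengths):
        cid = f"tx{i:05d}"
        seq = _random_seq(rng, L)
        contigs.append(Contig(cid, seq))
        pieces[cid] = seq
    remaining = genome_size - total
    j = 0
    while remaining > 0:
        L = min(intergenic_piece, remaining)
        if L < read_length:
            break
        pieces[f"ig{j:05d}"] = _random_seq(rng, L)
        remaining -= L
        j += 1

    config = SimConfig(
        coverage=coverage,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
    reads, origins = simulate_genomic_reads(pieces, config)
    total_read_bases = len(reads) * read_length
    contig_ids = set(pieces) - {k for k in pieces if k.startswith("ig")}
    by_read = {
        aln.read_id: [aln]
        for aln in true_alignments(
            (o for o in origins if o.contig in contig_ids), pieces, read_length
        )
    }
    summary = coverage_summary(by_read, contigs, total_read_bases)
    return GenomeSizeExperiment(
        true_genome_size=genome_size,
        transcriptome_bp=total,
        total_read_bases=total_read_bases,
        summary=summary,
    )
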