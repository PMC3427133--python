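"""Synthetic diploid-transcriptome generator with recorded ground truth.

The generator emulates the inputs of the real study so that every
downstream stage (trimming, pileup, variant calling, genome sizing,
paired-end validation, hairpin repair) can be tested against a known
truth table without downloading anything:

* contig lengths follow a right-skewed log-normal law floored at 200 bp
  (median ~453 bp, mean ~770 bp, capped at ~13 kb), matching the
  published assembly's length profile;
* the animal is a clonal diploid: haplotype A equals the reference
  contig, haplotype B carries heterozygous SNVs at ~1 per 808 bp with a
  transition:transversion ratio defaulting to 1.6, plus short indels
  (sizes 1-8 with monotonically decreasing weights);
* genomic short reads are drawn uniformly from the haplotypes with a
  uniform per-base substitution error rate and constant Q40 qualities;
* long "Sanger-like" read pairs come from opposite ends of a contig.

Every generator is a pure function of (inputs, seed).  Read provenance
(source sequence, haplotype, offset, strand, error positions) is
recorded so that exact truth alignments can be reconstructed by
:func:`true_alignments` — this is what lets recovery tests interrogate
the variant caller without coupling them to the heuristic aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ConfigError
from .seqio import Contig, QualityRead, decode_bases, reverse_complement

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"

#: Default indel size weights (sizes 1..8), proportional to the observed
#: indel-size spectrum of the study system; strictly decreasing.
DEFAULT_INDEL_SIZE_WEIGHTS = (5773, 1289, 862, 372, 165, 143, 57, 30)


@dataclass
class SimConfig:
    """Parameters of the synthetic diploid transcriptome.

    Defaults are the study conditions: heterozygosity 1/808 per bp,
    Ts/Tv 1.6, indel rate 8,691 per 44.7 Mb, 100 bp reads, Q40 bases,
    0.5% substitution error.
    """

    n_contigs: int = 100
    length_log_mean: float = math.log(453.0)
    length_log_sd: float = 1.03
    min_contig_len: int = 200
    max_contig_len: int = 13_061
    snv_rate: float = 1.0 / 808.0
    tstv_ratio: float = 1.6
    indel_rate: float = 8_691 / 44_700_000
    indel_size_weights: Sequence[float] = DEFAULT_INDEL_SIZE_WEIGHTS
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.005
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snv_rate", "indel_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        if self.min_contig_len < 200:
            raise ConfigError(
                "contigs shorter than the 200 bp floor cannot be requested"
            )
        if self.max_contig_len < self.min_contig_len:
            raise ConfigError("max_contig_len < min_contig_len")
        w = list(self.indel_size_weights)
        if len(w) != 8 or any(b > a for a, b in zip(w, w[1:])) or min(w) < 0:
            raise ConfigError(
                "indel_size_weights must be 8 nonincreasing nonnegative weights"
            )
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if not 0 <= self.base_quality <= 60:
            raise ConfigError("base_quality must be in [0, 60]")


class PlantedVariant(NamedTuple):
    """One planted heterozygous variant, in reference coordinates.

    For SNVs ``ref``/``alt`` are single bases at ``pos``.  Indels use the
    VCF anchoring convention: ``pos`` is the 0-based left-flank anchor,
    ``ref``/``alt`` both start with the anchor base.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    var_class: str  # transition | transversion | indel


@dataclass
class TruthTable:
    """Ground truth of a simulation run."""

    variants: list[PlantedVariant] = field(default_factory=list)
    genome_size: int | None = None
    hairpins: list[tuple[str, int]] = field(default_factory=list)

    def snvs(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.var_class != "indel"]

    def indels(self) -> list[PlantedVariant]:
        return [v for v in self.variants if v.var_class == "indel"]


@dataclass(frozen=True)
class HaplotypeMap:
    """Block map from haplotype-B coordinates to reference coordinates.

    ``blocks`` is an ordered tuple of (b_start, ref_start, length);
    inserted bases fall between blocks, deleted reference bases appear
    as jumps in ``ref_start``.  ``snv_positions`` are the reference
    coordinates of planted substitutions (sorted).
    """

    blocks: tuple[tuple[int, int, int], ...]
    snv_positions: tuple[int, ...]


@dataclass(frozen=True)
class HaplotypePair:
    """The two haplotype sequences of one contig (A == reference)."""

    a: str
    b: str
    b_map: HaplotypeMap


class ReadOrigin(NamedTuple):
    """Provenance of one simulated read.

    ``start`` and ``error_offsets`` are in coordinates of the sampled
    fragment on its source haplotype (before any reverse-complementing
    for minus-strand reads).
    """

    read_id: str
    contig: str
    hap: str  # "A" | "B" | "-" (haploid piece)
    start: int
    strand: str  # "+" | "-"
    error_offsets: tuple[int, ...]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return decode_bases(rng.integers(0, 4, size=length).astype(np.uint8))


def _sample_lengths(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Right-skewed contig lengths, resampled into [min, max]."""
    out = np.empty(config.n_contigs, dtype=np.int64)
    filled = 0
    while filled < config.n_contigs:
        draw = rng.lognormal(
            config.length_log_mean, config.length_log_sd, size=config.n_contigs
        ).astype(np.int64)
        ok = draw[(draw >= config.min_contig_len) & (draw <= config.max_contig_len)]
        take = min(len(ok), config.n_contigs - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _plant_variants(
    rng: np.random.Generator, cid: str, seq: str, config: SimConfig
) -> tuple[list[PlantedVariant], str, HaplotypeMap]:
    """Plant SNVs/indels on haplotype B; return (truth, hapB, map)."""
    L = len(seq)
    p_ts = config.tstv_ratio / (1.0 + config.tstv_ratio)
    snv_pos = np.flatnonzero(rng.random(L) < config.snv_rate)
    # Indels stay clear of contig ends (read-length margin) so recovery
    # tests are free of edge-effect ambiguity.
    margin = config.read_length
    if L > 2 * margin + 20:
        cand = np.flatnonzero(rng.random(L) < config.indel_rate)
        indel_pos = cand[(cand >= margin) & (cand < L - margin - 10)]
    else:
        indel_pos = np.empty(0, dtype=np.int64)

    # Merge, keeping a minimum spacing of 15 bp so variants never interact.
    events: list[tuple[int, str]] = sorted(
        [(int(p), "snv") for p in snv_pos] + [(int(p), "indel") for p in indel_pos]
    )
    kept: list[tuple[int, str]] = []
    last = -10**9
    for pos, kind in events:
        if pos - last >= 15:
            kept.append((pos, kind))
            last = pos

    variants: list[PlantedVariant] = []
    hap = bytearray(seq, "ascii")
    indels: list[tuple[int, str, str]] = []  # (anchor, kind, payload)
    sizes = np.arange(1, 9)
    w = np.asarray(config.indel_size_weights, dtype=float)
    size_p = w / w.sum() if w.sum() > 0 else np.full(8, 1 / 8)

    for pos, kind in kept:
        ref_base = seq[pos]
        if ref_base == "N":
            continue
        if kind == "snv":
            if rng.random() < p_ts:
                alt = _TRANSITION[ref_base]
                var_class = "transition"
            else:
                choices = [
                    b for b in _BASES if b != ref_base and b != _TRANSITION[ref_base]
                ]
                alt = choices[int(rng.integers(0, 2))]
                var_class = "transversion"
            hap[pos] = ord(alt)
            variants.append(PlantedVariant(cid, pos, ref_base, alt, "%s" % var_class))
        else:
            size = int(rng.choice(sizes, p=size_p))
            anchor = pos
            anchor_base = seq[anchor]
            if rng.random() < 0.5 and anchor + 1 + size < L - margin:
                # deletion of seq[anchor+1 : anchor+1+size]
                deleted = seq[anchor + 1 : anchor + 1 + size]
                if "N" in deleted:
                    continue
                variants.append(
                    PlantedVariant(
                        cid, anchor, anchor_base + deleted, anchor_base, "indel"
                    )
                )
                indels.append((anchor, "D", deleted))
            else:
                ins = _random_seq(rng, size)
                variants.append(
                    PlantedVariant(
                        cid, anchor, anchor_base, anchor_base + ins, "indel"
                    )
                )
                indels.append((anchor, "I", ins))

    # Build haplotype B and its block map by walking the indels.
    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    hap_str = hap.decode("ascii")
    b = r = 0
    for anchor, kind, payload in indels:
        seg_len = anchor + 1 - r
        parts.append(hap_str[r : anchor + 1])
        blocks.append((b, r, seg_len))
        b += seg_len
        r = anchor + 1
        if kind == "D":
            r += len(payload)
        else:
            parts.append(payload)
            b += len(payload)
    if r < L:
        parts.append(hap_str[r:])
        blocks.append((b, r, L - r))
    hap_b = "".join(parts)
    b_map = HaplotypeMap(
        blocks=tuple(blocks),
        snv_positions=tuple(
            int(v.pos) for v in variants if v.var_class != "indel"
        ),
    )
    return variants, hap_b, b_map


def simulate_diploid_transcriptome(
    config: SimConfig,
) -> tuple[list[Contig], dict[str, HaplotypePair], TruthTable]:
    """Simulate reference contigs plus a diploid haplotype pair per contig.

    Haplotype A equals the reference; haplotype B carries the planted
    variants listed (exhaustively) in the returned :class:`TruthTable`.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _sample_lengths(rng, config)
    contigs: list[Contig] = []
    haplotypes: dict[str, HaplotypePair] = {}
    truth = TruthTable()
    for i, L in enumerate(lengths):
        cid = f"contig{i:05d}"
        seq = _random_seq(rng, int(L))
        variants, hap_b, b_map = _plant_variants(rng, cid, seq, config)
        contigs.append(Contig(cid, seq))
        haplotypes[cid] = HaplotypePair(a=seq, b=hap_b, b_map=b_map)
        truth.variants.extend(variants)
    return contigs, haplotypes, truth


def _mutate_fragment(
    rng: np.random.Generator, frag: str, n_err: int
) -> tuple[str, tuple[int, ...]]:
    """Apply ``n_err`` substitution errors at distinct random offsets."""
    offsets = rng.choice(len(frag), size=min(n_err, len(frag)), replace=False)
    buf = bytearray(frag, "ascii")
    for off in offsets:
        orig = chr(buf[off])
        alts = [b for b in _BASES if b != orig]
        buf[off] = ord(alts[int(rng.integers(0, 3))])
    return buf.decode("ascii"), tuple(int(o) for o in sorted(offsets))


def simulate_genomic_reads(
    haplotypes: Mapping[str, HaplotypePair | str],
    config: SimConfig,
    id_prefix: str = "g",
) -> tuple[list[QualityRead], list[ReadOrigin]]:
    """Simulate uniform-coverage genomic reads from haplotype sequences.

    ``haplotypes`` maps a sequence name either to a :class:`HaplotypePair`
    (both haplotypes sampled in equal proportion) or to a plain string (a
    haploid piece, e.g. for genome-size experiments).  The total number
    of emitted bases is ``coverage`` times the total haplotype length;
    read starts are uniform within each sequence, strands are random, and
    each base is substituted with probability ``error_rate``.  Qualities
    are constant ``base_quality``.  Returns (reads, provenance).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    rl = config.read_length
    pieces: list[tuple[str, str, str]] = []  # (contig, hap-tag, sequence)
    for name, hp in haplotypes.items():
        if isinstance(hp, HaplotypePair):
            pieces.append((name, "A", hp.a))
            pieces.append((name, "B", hp.b))
        else:
            pieces.append((name, "-", hp))
    shortest = min(len(seq) for _, _, seq in pieces)
    if rl > shortest:
        raise ConfigError(
            f"read_length {rl} exceeds the shortest haplotype sequence ({shortest} bp)"
        )

    shared_quals = np.full(rl, config.base_quality, dtype=np.int64)
    reads: list[QualityRead] = []
    origins: list[ReadOrigin] = []
    counter = 0
    for name, hap, seq in pieces:
        L = len(seq)
        n_reads = int(rng.poisson(config.coverage * L / rl))
        if n_reads == 0:
            continue
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        if config.error_rate > 0:
            n_err = rng.binomial(rl, config.error_rate, size=n_reads)
        else:
            n_err = np.zeros(n_reads, dtype=np.int64)
        for j in range(n_reads):
            s = int(starts[j])
            frag = seq[s : s + rl]
            err_offsets: tuple[int, ...] = ()
            if n_err[j]:
                frag, err_offsets = _mutate_fragment(rng, frag, int(n_err[j]))
            strand = "-" if strands[j] else "+"
            bases = reverse_complement(frag) if strand == "-" else frag
            rid = f"{id_prefix}{counter:08d}"
            counter += 1
            reads.append(QualityRead(rid, bases, shared_quals))
            origins.append(ReadOrigin(rid, name, hap, s, strand, err_offsets))
    return reads, origins


def true_alignments(
    origins: Iterable[ReadOrigin],
    haplotypes: Mapping[str, HaplotypePair | str],
    read_length: int,
):
    """Yield exact truth BlockAlignments for simulated reads.

    Haplotype-A (and haploid) reads map as a single full-length block.
    Haplotype-B reads are projected through the planted-indel block map,
    so deletions appear as reference jumps and inserted bases as read
    jumps.  ``matches`` is computed as aligned bases minus planted-SNV
    positions covered minus injected errors — a tight lower bound (an
    error landing on a planted SNV or inside an insertion is still
    counted as a mismatch), which is what the validity filter needs.

    Yields :class:`polyptome.mapcov.BlockAlignment` objects; imported
    lazily to keep module dependencies one-way.
    """
    from .mapcov import BlockAlignment  # local import: avoid cycle

    rl = read_length
    for org in origins:
        hp = haplotypes[org.contig]
        if not isinstance(hp, HaplotypePair) or org.hap in ("A", "-"):
            blocks = ((0, org.start, rl),)
            matches = rl - len(org.error_offsets)
            yield BlockAlignment(
                read_id=org.read_id,
                contig_id=org.contig,
                strand=org.strand,
                blocks=blocks,
                matches=matches,
                aligned_bases=rl,
                gaps=0,
            )
            continue
        # Haplotype B: intersect [start, start+rl) with the block map.
        b_lo, b_hi = org.start, org.start + rl
        blocks = []
        aligned = 0
        n_snv = 0
        snvs = hp.b_map.snv_positions
        for b_start, r_start, length in hp.b_map.blocks:
            lo = max(b_lo, b_start)
            hi = min(b_hi, b_start + length)
            if hi <= lo:
                continue
            read_off = lo - b_lo
            ref_off = r_start + (lo - b_start)
            blk_len = hi - lo
            blocks.append((read_off, ref_off, blk_len))
            aligned += blk_len
            for p in snvs:  # snv lists are short; linear scan is fine
                if ref_off <= p < ref_off + blk_len:
                    n_snv += 1
        if not blocks:
            continue
        gaps = len(blocks) - 1
        matches = aligned - n_snv - len(org.error_offsets)
        yield BlockAlignment(
            read_id=org.read_id,
            contig_id=org.contig,
            strand=org.strand,
            blocks=tuple(blocks),
            matches=max(matches, 0),
            aligned_bases=aligned,
            gaps=gaps,
        )


def simulate_sanger_pairs(
    contigs: Sequence[Contig],
    n_pairs: int,
    insert_mean: float,
    insert_sd: float,
    read_length: int,
    seed: int,
    base_quality: int = 40,
) -> tuple[list[tuple[QualityRead, QualityRead]], list[str]]:
    """Simulate long paired end reads from opposite ends of contigs.

    The forward read covers the 5' end of a sampled insert on the plus
    strand; the reverse read covers the 3' end on the minus strand of
    the same source contig.  Returns (pairs, source contig ids).
    """
    rng = np.random.default_rng(seed)
    eligible = [c for c in contigs if c.length > read_length + 1]
    if not eligible:
        raise ConfigError("no contig long enough for the requested reads")
    quals = np.full(read_length, base_quality, dtype=np.int64)
    pairs: list[tuple[QualityRead, QualityRead]] = []
    sources: list[str] = []
    weights = np.array([c.length for c in eligible], dtype=float)
    weights /= weights.sum()
    for i in range(n_pairs):
        c = eligible[int(rng.choice(len(eligible), p=weights))]
        insert = int(np.clip(rng.normal(insert_mean, insert_sd), read_length + 1, c.length))
        start = int(rng.integers(0, c.length - insert + 1))
        frag = c.seq[start : start + insert]
        fwd = QualityRead(f"s{i:05d}.f", frag[:read_length], quals)
        rev = QualityRead(
            f"s{i:05d}.r", reverse_complement(frag[-read_length:]), quals
        )
        pairs.append((fwd, rev))
        sources.append(c.id)
    return pairs, sources


def inject_hairpin(
    contig: Contig, arm_length: int, seed: int = 0, mutation_rate: float = 0.0
) -> tuple[Contig, int]:
    """Turn a contig prefix into a hairpin: arm + reverse complement(arm).

    The returned contig is ``s + revcomp(s)`` for ``s`` the first
    ``arm_length`` bases; the apex (fold point) is ``arm_length``.
    ``mutation_rate`` optionally mutates second-arm positions to emulate
    a near-palindrome.  ``arm_length`` 0 returns the input unchanged.
    """
    if arm_length < 0:
        raise ConfigError("arm_length must be >= 0")
    if arm_length == 0:
        return contig, 0
    arm = contig.seq[:arm_length]
    second = reverse_complement(arm)
    if mutation_rate > 0:
        rng = np.random.default_rng(seed)
        buf = bytearray(second, "ascii")
        for pos in np.flatnonzero(rng.random(len(buf)) < mutation_rate):
            orig = chr(buf[pos])
            alts = [b for b in _BASES if b != orig]
            buf[pos] = ord(alts[int(rng.integers(0, 3))])
        second = buf.decode("ascii")
    return Contig(contig.id + ".hp", arm + second), arm_length


def write_truth_table(truth: TruthTable, path: str) -> None:
    """Write planted variants as a TSV (contig, pos, ref, alt, class)."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tclass\n")
        for v in truth.variants:
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.var_class}\n")
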