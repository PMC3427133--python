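"""Block alignments, validity filtering, pileups, coverage and genome size.

The genome-size method: map genomic reads to the transcriptome, give
every contig a mean coverage (aligned bases / contig length, counting
only each read's best un-gapped hit), take the modal coverage across
contigs as the sequencing depth, and divide the total genomic read bases
by that depth.  The transcriptome acts as a random sample of genomic
loci, so the mode of the per-contig coverages estimates genome-wide
depth without a genome assembly.

Alignment validity follows the published rule: an optimal alignment is
valid when at least 40% of the read aligned with >= 96% agreement
(boundaries inclusive).  The permissive 40% floor tolerates reads that
straddle exon-intron boundaries.

``align_read_to_contig`` is a k-mer-seeded exact local aligner: seeds
only nominate candidate strands, the alignment itself is a full
Smith-Waterman with linear gap costs (match +1, mismatch -1, gap -2 per
base), so scores agree with any exhaustive implementation by
construction.  Coordinates are 0-based half-open throughout; conversion
happens only at format boundaries.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EstimationError, FormatError, InputError
from .seqio import Contig, QualityRead, encode_bases, reverse_complement

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2  # linear, per gapped base


@dataclass(frozen=True)
class BlockAlignment:
    """A read-to-contig alignment as ordered co-linear blocks.

    ``blocks`` are (read_start, contig_start, length) triples in 0-based
    half-open coordinates; for minus-strand alignments the read
    coordinates index the reverse-complemented read.  ``matches`` counts
    matching bases, ``aligned_bases`` equals the sum of block lengths,
    ``gaps`` counts gap openings.
    """

    read_id: str
    contig_id: str
    strand: str
    blocks: tuple[tuple[int, int, int], ...]
    matches: int
    aligned_bases: int
    gaps: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.aligned_bases != sum(b[2] for b in self.blocks):
            raise InputError("aligned_bases must equal the sum of block lengths")
        if self.matches > self.aligned_bases:
            raise InputError("matches cannot exceed aligned_bases")

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_bases if self.aligned_bases else 0.0

    @property
    def score(self) -> int:
        mismatches = self.aligned_bases - self.matches
        gap_bases = sum(
            (b2[1] - (b1[1] + b1[2])) + (b2[0] - (b1[0] + b1[2]))
            for b1, b2 in zip(self.blocks, self.blocks[1:])
        )
        return (
            MATCH_SCORE * self.matches
            + MISMATCH_SCORE * mismatches
            + GAP_SCORE * gap_bases
        )


def _smith_waterman(read_codes: np.ndarray, contig_codes: np.ndarray):
    """Exact local DP with linear gap cost; returns (H matrix, best score).

    Row recurrence vectorised over the contig axis.  Horizontal moves
    with a linear gap cost reduce to a prefix-maximum over the
    pre-horizontal row values, which keeps the inner loop in numpy.
    """
    n, m = len(read_codes), len(contig_codes)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jj = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        rc = read_codes[i - 1]
        match_row = np.where(
            (contig_codes == rc) & (rc < 4), MATCH_SCORE, MISMATCH_SCORE
        )
        diag = H[i - 1, :-1] + match_row
        up = H[i - 1, 1:] + GAP_SCORE
        h0 = np.maximum(np.maximum(diag, up), 0)
        # left moves: H[i,j] = max(h0[j], max_{k<j}(h0[k] - GAP*(j-k)))
        a = h0 + (-GAP_SCORE) * jj
        run = np.maximum.accumulate(a)
        left = np.empty_like(h0)
        left[0] = h0[0]
        left[1:] = np.maximum(h0[1:], run[:-1] + GAP_SCORE * jj[1:])
        H[i, 1:] = left
    return H, int(H.max())


def _traceback(
    H: np.ndarray, read_codes: np.ndarray, contig_codes: np.ndarray, i: int, j: int
):
    """Greedy traceback from (i, j); returns (blocks, matches, read0, contig0)."""
    path: list[tuple[int, int, bool]] = []  # (read_pos, contig_pos, is_diag)
    while i > 0 and j > 0 and H[i, j] > 0:
        rc, cc = read_codes[i - 1], contig_codes[j - 1]
        s = MATCH_SCORE if (rc == cc and rc < 4) else MISMATCH_SCORE
        if H[i, j] == H[i - 1, j - 1] + s:
            path.append((i - 1, j - 1, True))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP_SCORE:
            i -= 1
        else:
            j -= 1
    path.reverse()
    blocks: list[list[int]] = []
    matches = 0
    for rp, cp, _ in path:
        if blocks and rp == blocks[-1][0] + blocks[-1][2] and cp == blocks[-1][1] + blocks[-1][2]:
            blocks[-1][2] += 1
        else:
            blocks.append([rp, cp, 1])
        if read_codes[rp] == contig_codes[cp] and read_codes[rp] < 4:
            matches += 1
    return [tuple(b) for b in blocks], matches


def _seed_hit(read_codes: np.ndarray, contig_kmers: set, k: int) -> bool:
    if len(read_codes) < k:
        return False
    for off in range(0, len(read_codes) - k + 1, max(1, k // 2)):
        window = read_codes[off : off + k]
        if window.max() < 4 and window.tobytes() in contig_kmers:
            return True
    return False


def _contig_kmer_set(contig_codes: np.ndarray, k: int) -> set:
    kmers: set = set()
    buf = contig_codes.tobytes()
    for i in range(len(contig_codes) - k + 1):
        kmers.add(buf[i : i + k])
    return kmers


def align_read_to_contig(
    read: QualityRead | str,
    contig: Contig,
    seed_k: int = 13,
    min_score: int = 16,
) -> BlockAlignment | None:
    """Best local alignment of a read against one contig, or None.

    Both strands are tried; a strand is only aligned when it shares at
    least one exact ``seed_k``-mer with the contig.  Among equal-scoring
    cells, plus strand and then the leftmost contig coordinate win, so
    the result is deterministic.
    """
    bases = read.bases if isinstance(read, QualityRead) else read
    rid = read.id if isinstance(read, QualityRead) else "read"
    if len(bases) < 20:
        raise InputError("reads shorter than 20 bp are not alignable")
    contig_codes = encode_bases(contig.seq)
    kmers = _contig_kmer_set(contig_codes, seed_k)
    best: tuple[int, int, str, np.ndarray, np.ndarray] | None = None
    for strand in "+-":
        seq = bases if strand == "+" else reverse_complement(bases)
        read_codes = encode_bases(seq)
        if not _seed_hit(read_codes, kmers, seed_k):
            continue
        H, score = _smith_waterman(read_codes, contig_codes)
        if score < min_score:
            continue
        cells = np.argwhere(H == score)
        i, j = min(cells.tolist(), key=lambda c: (c[1], c[0]))
        if best is None or score > best[0] or (score == best[0] and j < best[1]):
            best = (score, int(j), strand, H, read_codes)
    if best is None:
        return None
    score, j_end, strand, H, read_codes = best
    cells = np.argwhere(H == score)
    i, j = min(cells.tolist(), key=lambda c: (c[1], c[0]))
    blocks, matches = _traceback(H, read_codes, contig_codes, int(i), int(j))
    if not blocks:
        return None
    aligned = sum(b[2] for b in blocks)
    return BlockAlignment(
        read_id=rid,
        contig_id=contig.id,
        strand=strand,
        blocks=tuple(blocks),
        matches=matches,
        aligned_bases=aligned,
        gaps=len(blocks) - 1,
    )


def is_valid_alignment(
    aln: BlockAlignment,
    read_length: int,
    min_frac: float = 0.40,
    min_ident: float = 0.96,
) -> bool:
    """Published validity rule, boundaries inclusive.

    Valid iff ``aligned_bases >= min_frac * read_length`` and
    ``matches / aligned_bases >= min_ident``.  The read length is the
    post-trimming length.
    """
    if aln.aligned_bases == 0:
        return False
    frac_ok = aln.aligned_bases >= min_frac * read_length - 1e-9
    ident_ok = aln.matches >= min_ident * aln.aligned_bases - 1e-9
    return bool(frac_ok and ident_ok)


class Pileup:
    """Per-contig, per-position base counts plus indel-opening tallies.

    Base counts are a (4, L) int32 array per contig (rows A, C, G, T; N
    bases are not counted).  Indel openings are tallied at their
    left-flanking contig position as ``{pos: {descriptor: count}}`` where
    a descriptor is ``("I", inserted_seq)`` or ``("D", deleted_len)``.
    """

    def __init__(self, contigs: Iterable[Contig]):
        self.counts: dict[str, np.ndarray] = {
            c.id: np.zeros((4, c.length), dtype=np.int32) for c in contigs
        }
        self.indels: dict[str, dict[int, dict[tuple, int]]] = {
            cid: {} for cid in self.counts
        }

    def depth(self, contig_id: str) -> np.ndarray:
        return self.counts[contig_id].sum(axis=0)

    def add_base_batch(
        self, contig_id: str, positions: np.ndarray, codes: np.ndarray
    ) -> None:
        keep = codes < 4
        np.add.at(self.counts[contig_id], (codes[keep], positions[keep]), 1)

    def add_indel(self, contig_id: str, pos: int, descriptor: tuple) -> None:
        site = self.indels[contig_id].setdefault(pos, {})
        site[descriptor] = site.get(descriptor, 0) + 1


def build_pileup(
    alignments: Iterable[BlockAlignment],
    contigs: Sequence[Contig],
    reads: Mapping[str, QualityRead | str],
    batch_bases: int = 4_000_000,
) -> Pileup:
    """Accumulate valid alignments into a pileup.

    Every aligned read base increments its base's count at the mapped
    contig position (minus-strand reads contribute via their reverse
    complement, matching the block convention).  Gaps between blocks are
    tallied as indel openings at the left-flanking position.
    """
    pile = Pileup(contigs)
    pending_pos: dict[str, list[np.ndarray]] = {cid: [] for cid in pile.counts}
    pending_code: dict[str, list[np.ndarray]] = {cid: [] for cid in pile.counts}
    pending_n = 0

    def flush() -> None:
        nonlocal pending_n
        for cid in pending_pos:
            if pending_pos[cid]:
                pos = np.concatenate(pending_pos[cid])
                codes = np.concatenate(pending_code[cid])
                pile.add_base_batch(cid, pos, codes)
                pending_pos[cid].clear()
                pending_code[cid].clear()
        pending_n = 0

    for aln in alignments:
        if aln.contig_id not in pile.counts:
            raise InputError(f"alignment references unknown contig {aln.contig_id!r}")
        read = reads[aln.read_id]
        bases = read.bases if isinstance(read, QualityRead) else read
        if aln.strand == "-":
            bases = reverse_complement(bases)
        codes = encode_bases(bases)
        for rs, cs, length in aln.blocks:
            pending_pos[aln.contig_id].append(
                np.arange(cs, cs + length, dtype=np.int64)
            )
            pending_code[aln.contig_id].append(codes[rs : rs + length])
            pending_n += length
        for (rs1, cs1, l1), (rs2, cs2, l2) in zip(aln.blocks, aln.blocks[1:]):
            anchor = cs1 + l1 - 1
            if cs2 > cs1 + l1:  # deletion in read relative to contig
                pile.add_indel(aln.contig_id, anchor, ("D", cs2 - (cs1 + l1)))
            if rs2 > rs1 + l1:  # insertion in read relative to contig
                pile.add_indel(
                    aln.contig_id, anchor, ("I", bases[rs1 + l1 : rs2])
                )
        if pending_n >= batch_bases:
            flush()
    flush()
    return pile


def assign_best_hits(
    alignments_by_read: Mapping[str, Sequence[BlockAlignment]],
    exclude_gapped: bool = True,
) -> list[BlockAlignment]:
    """One best alignment per read for coverage accounting.

    Gapped alignments are excluded (the published rule counts only
    gap-free top hits); ties on score keep the first listed.
    """
    chosen: list[BlockAlignment] = []
    for rid, alns in alignments_by_read.items():
        pool = [a for a in alns if not (exclude_gapped and a.gaps > 0)]
        if not pool:
            continue
        chosen.append(max(pool, key=lambda a: a.score))  # max keeps first on ties
    return chosen


def contig_mean_coverage(
    alignments: Iterable[BlockAlignment], contig: Contig
) -> float:
    """Sum of aligned bases mapped to this contig divided by its length."""
    total = sum(a.aligned_bases for a in alignments if a.contig_id == contig.id)
    return total / contig.length


def modal_coverage(per_contig_means: Iterable[float]) -> int:
    """Mode of integer-rounded per-contig coverages (half-up rounding).

    Zero-coverage contigs are excluded; ties break toward the lower
    value.  All-zero input raises :class:`EstimationError`.
    """
    means = np.asarray([m for m in per_contig_means if m > 0], dtype=float)
    if means.size == 0:
        raise EstimationError("no contig has nonzero coverage")
    rounded = np.floor(means + 0.5).astype(np.int64)
    rounded = rounded[rounded >= 1]
    if rounded.size == 0:
        raise EstimationError("all rounded coverages are zero")
    counts = np.bincount(rounded)
    return int(counts.argmax())  # argmax returns the lowest index on ties


def estimate_genome_size(total_genomic_bases: float, modal_cov: int) -> float:
    """Total genomic read bases divided by the modal (depth) coverage."""
    if modal_cov < 1:
        raise EstimationError("modal coverage must be >= 1")
    return total_genomic_bases / modal_cov


@dataclass
class CoverageSummary:
    """Per-contig mean coverages plus the dataset-level genome estimate."""

    per_contig: dict[str, float]
    modal: int
    total_genomic_bases: int
    genome_size: float

    def to_dict(self) -> dict:
        return {
            "modal_coverage": self.modal,
            "total_genomic_bases": self.total_genomic_bases,
            "genome_size_bp": self.genome_size,
            "n_contigs": len(self.per_contig),
        }


def coverage_summary(
    alignments_by_read: Mapping[str, Sequence[BlockAlignment]],
    contigs: Sequence[Contig],
    total_genomic_bases: int,
) -> CoverageSummary:
    """Best-hit coverage per contig, modal coverage and genome size."""
    best = assign_best_hits(alignments_by_read)
    sums: dict[str, int] = {c.id: 0 for c in contigs}
    for aln in best:
        if aln.contig_id not in sums:
            raise InputError(f"alignment references unknown contig {aln.contig_id!r}")
        sums[aln.contig_id] += aln.aligned_bases
    per_contig = {c.id: sums[c.id] / c.length for c in contigs}
    modal = modal_coverage(per_contig.values())
    size = estimate_genome_size(total_genomic_bases, modal)
    return CoverageSummary(
        per_contig=per_contig,
        modal=modal,
        total_genomic_bases=total_genomic_bases,
        genome_size=size,
    )


# ---------------------------------------------------------------------------
# Alignment file formats: PSL-like TSV and SAM
# ---------------------------------------------------------------------------

_TSV_HEADER = "read\tcontig\tstrand\tmatches\taligned\tgaps\tblocks"


def write_alignments_tsv(
    alignments: Iterable[BlockAlignment], path: str | os.PathLike
) -> None:
    """Write alignments as a PSL-like TSV (blocks as rs:cs:len triples)."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for a in alignments:
            blocks = ",".join(f"{rs}:{cs}:{ln}" for rs, cs, ln in a.blocks)
            fh.write(
                f"{a.read_id}\t{a.contig_id}\t{a.strand}\t{a.matches}\t"
                f"{a.aligned_bases}\t{a.gaps}\t{blocks}\n"
            )


def read_alignments_tsv(path: str | os.PathLike) -> list[BlockAlignment]:
    """Read the PSL-like TSV written by :func:`write_alignments_tsv`."""
    out: list[BlockAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise FormatError(f"{path}: unexpected alignment TSV header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            rid, cid, strand, matches, aligned, gaps, blockstr = fields
            blocks = tuple(
                tuple(int(x) for x in blk.split(":"))
                for blk in blockstr.split(",")
                if blk
            )
            out.append(
                BlockAlignment(
                    read_id=rid,
                    contig_id=cid,
                    strand=strand,
                    blocks=blocks,  # type: ignore[arg-type]
                    matches=int(matches),
                    aligned_bases=int(aligned),
                    gaps=int(gaps),
                )
            )
    return out


def read_sam(path: str | os.PathLike) -> list[BlockAlignment]:
    """Read block alignments from a (text) SAM file via pysam.

    CIGAR M/=/X advance both sequences (one block run), I advances the
    read, D advances the reference.  ``matches`` is derived from the NM
    tag when present (NM minus gapped bases), otherwise the aligned-base
    count is used as an upper bound.
    """
    import pysam

    out: list[BlockAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            blocks: list[tuple[int, int, int]] = []
            rpos, cpos = 0, rec.reference_start
            ins_bases = del_bases = 0
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    blocks.append((rpos, cpos, length))
                    rpos += length
                    cpos += length
                elif op == 1:  # I
                    rpos += length
                    ins_bases += length
                elif op == 2:  # D
                    cpos += length
                    del_bases += length
                elif op == 4:  # S
                    rpos += length
            aligned = sum(b[2] for b in blocks)
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
                matches = max(aligned - (int(nm) - ins_bases - del_bases), 0)
            else:
                matches = aligned
            out.append(
                BlockAlignment(
                    read_id=rec.query_name,
                    contig_id=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    blocks=tuple(blocks),
                    matches=matches,
                    aligned_bases=aligned,
                    gaps=len(blocks) - 1 if blocks else 0,
                )
            )
    return out


def write_coverage_tsv(summary: CoverageSummary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tmean_coverage\n")
        for cid, cov in summary.per_contig.items():
            fh.write(f"{cid}\t{cov:.4f}\n")


def write_coverage_json(summary: CoverageSummary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
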