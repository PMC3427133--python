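"""Threshold-based heterozygous SNV/indel calling and spectrum summaries.

The caller implements the published rule directly: at any pileup site
with depth >= 10 where the most frequent non-reference base accounts for
>= 35% of the reads, that base is called as a heterozygous SNV (both
boundaries inclusive).  Indels are called the same way from the
indel-opening tallies at their left-flanking position.  The 35% floor is
what separates heterozygous sites (alternative fraction ~50% in a clonal
diploid) from sequencing errors.

The alternative fraction is computed over the *total* site depth, not
over ref+alt only — the most literal reading of the rule — and only the
top alternative base is considered (the variants are framed as
biallelic).  Sites where the reference base itself falls below the
threshold are still reported as a single SNV, flagged
``ref_below_frac``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, ParameterError
from .mapcov import Pileup
from .seqio import Contig, encode_bases

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_SNV_CLASSES = ("A/G", "C/T", "A/C", "G/C", "A/T", "G/T")
_BASES = "ACGT"


@dataclass(frozen=True)
class VariantCall:
    """A called site.

    SNVs: ``ref``/``alt`` are single bases at 0-based ``pos``.  Indels
    use VCF-style anchoring: ``pos`` is the left-flank position and both
    alleles start with the anchor base.  ``alt_fraction`` is the calling
    fraction over total site depth.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    var_class: str  # transition | transversion | indel
    ref_below_frac: bool = False

    @property
    def is_indel(self) -> bool:
        return self.var_class == "indel"

    @property
    def indel_size(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def classify_substitution(ref: str, alt: str) -> str:
    """Transition ({A,G} or {C,T}) vs transversion, unordered."""
    if ref == alt:
        raise ParameterError("ref and alt must differ")
    if ref not in _BASES or alt not in _BASES:
        raise ParameterError(f"alleles must be in {{A,C,G,T}}: {ref!r}/{alt!r}")
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


def call_variants(
    pileup: Pileup,
    contigs: Sequence[Contig],
    min_cov: int = 10,
    min_frac: float = 0.35,
) -> list[VariantCall]:
    """Call heterozygous SNVs and indels from a pileup.

    At each site with depth >= ``min_cov``: the most frequent
    non-reference base (ties broken lexicographically) is called iff its
    fraction of total depth is >= ``min_frac``.  Indels are called at
    their anchor position iff the indel-opening count clears the same
    depth and fraction floors; the most common descriptor wins.
    Boundaries are inclusive.  Output is sorted by (contig, position).
    """
    calls: list[VariantCall] = []
    eps = 1e-9
    for contig in contigs:
        if contig.id not in pileup.counts:
            raise InputError(f"pileup has no data for contig {contig.id!r}")
        counts = pileup.counts[contig.id]
        if counts.shape[1] != contig.length:
            raise InputError(
                f"pileup/contig length mismatch for {contig.id!r}"
            )
        depth = counts.sum(axis=0)
        ref_codes = encode_bases(contig.seq)
        cols = np.arange(contig.length)
        known = ref_codes < 4
        alt_counts = counts.copy()
        alt_counts[ref_codes[known], cols[known]] = 0  # zero the reference row
        top_alt = alt_counts.max(axis=0)
        top_code = alt_counts.argmax(axis=0)  # first max = lexicographic tie-break
        callable_ = (
            known
            & (depth >= min_cov)
            & (top_alt > 0)
            & (top_alt >= min_frac * depth - eps)
        )
        ref_count = counts[ref_codes[known], cols[known]]
        ref_count_full = np.zeros(contig.length, dtype=np.int64)
        ref_count_full[known] = ref_count
        for pos in np.flatnonzero(callable_):
            ref_b = contig.seq[pos]
            alt_b = _BASES[int(top_code[pos])]
            d = int(depth[pos])
            calls.append(
                VariantCall(
                    contig=contig.id,
                    pos=int(pos),
                    ref=ref_b,
                    alt=alt_b,
                    depth=d,
                    alt_fraction=float(top_alt[pos] / d),
                    var_class=classify_substitution(ref_b, alt_b),
                    ref_below_frac=bool(ref_count_full[pos] < min_frac * d - eps),
                )
            )
        for pos, site in pileup.indels.get(contig.id, {}).items():
            d = int(depth[pos])
            total_events = sum(site.values())
            if d < min_cov or total_events < min_frac * d - eps:
                continue
            descriptor = max(site, key=lambda k: (site[k], k[0], str(k[1])))
            anchor = contig.seq[pos]
            if descriptor[0] == "I":
                ref_allele, alt_allele = anchor, anchor + descriptor[1]
            else:
                dlen = int(descriptor[1])
                end = min(pos + 1 + dlen, contig.length)
                ref_allele, alt_allele = anchor + contig.seq[pos + 1 : end], anchor
            calls.append(
                VariantCall(
                    contig=contig.id,
                    pos=int(pos),
                    ref=ref_allele,
                    alt=alt_allele,
                    depth=d,
                    alt_fraction=float(total_events / d),
                    var_class="indel",
                )
            )
    calls.sort(key=lambda c: (c.contig, c.pos))
    return calls


@dataclass
class VariantSummary:
    """Variant-spectrum summary in the layout of the published table."""

    snv_class_counts: dict[str, int]
    indel_count: int
    indel_size_histogram: dict[str, int]
    total_snvs: int
    density_bp: int | None  # bp per SNV; None when no SNVs

    @property
    def transitions(self) -> int:
        return self.snv_class_counts["A/G"] + self.snv_class_counts["C/T"]

    @property
    def transversions(self) -> int:
        return self.total_snvs - self.transitions


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for x >= 0)."""
    return int(np.floor(x + 0.5))


def snv_density(total_contig_bp: float, n_snvs: int) -> int | None:
    """bp per SNV, rounded half-up; None (undefined) when no SNVs."""
    if n_snvs == 0:
        return None
    return round_half_up(total_contig_bp / n_snvs)


def summarize_variants(
    calls: Iterable[VariantCall], total_contig_bp: float
) -> VariantSummary:
    """Tabulate SNV classes, indel sizes (1..8 plus overflow) and density."""
    class_counts = {k: 0 for k in _SNV_CLASSES}
    hist = {str(s): 0 for s in range(1, 9)}
    hist["8+"] = 0
    n_snv = n_indel = 0
    for call in calls:
        if call.is_indel:
            n_indel += 1
            size = call.indel_size
            hist[str(size) if size <= 8 else "8+"] += 1
        else:
            n_snv += 1
            key = "/".join(sorted((call.ref, call.alt)))
            if key == "C/G":
                key = "G/C"
            if key == "G/T" or key == "T/G":
                key = "G/T"
            class_counts[key] += 1
    return VariantSummary(
        snv_class_counts=class_counts,
        indel_count=n_indel,
        indel_size_histogram=hist,
        total_snvs=n_snv,
        density_bp=snv_density(total_contig_bp, n_snv),
    )


def write_summary_tsv(summary: VariantSummary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("variant_type\tcount\n")
        for key in _SNV_CLASSES:
            kind = "Transition" if key in ("A/G", "C/T") else "Transversion"
            fh.write(f"{key} {kind} SNV\t{summary.snv_class_counts[key]}\n")
        fh.write(f"Insertion or Deletion\t{summary.indel_count}\n")
        for size, count in summary.indel_size_histogram.items():
            fh.write(f"indel_size_{size}\t{count}\n")
        fh.write(f"total_SNVs\t{summary.total_snvs}\n")
        fh.write(f"bp_per_SNV\t{summary.density_bp}\n")


def write_vcf(
    calls: Sequence[VariantCall],
    contigs: Sequence[Contig],
    path: str | os.PathLike,
) -> None:
    """Write calls as minimal VCF 4.2 (1-based POS, DP/AF in INFO).

    Indels are left-anchored with the preceding reference base, which is
    already the internal representation.  Input must be sorted by
    (contig, position).
    """
    keys = [(c.contig, c.pos) for c in calls]
    if keys != sorted(keys):
        raise InputError("calls must be sorted by (contig, position)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyptome\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c.id},length={c.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative fraction">\n'
        )
        fh.write(
            '##INFO=<ID=RBF,Number=0,Type=Flag,Description="Reference below calling fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            info = f"DP={call.depth};AF={call.alt_fraction:.4f}"
            if call.ref_below_frac:
                info += ";RBF"
            fh.write(
                f"{call.contig}\t{call.pos + 1}\t.\t{call.ref}\t{call.alt}\t.\t"
                f"PASS\t{info}\n"
            )
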