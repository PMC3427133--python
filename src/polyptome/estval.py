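"""Paired-end concordance validation of an assembly.

Long paired reads sequenced from opposite ends of the same cDNA insert
should, in a well-assembled transcriptome, map to the same contig in
opposite orientations.  The validator classifies each pair:

* unmapped — either read has no alignment above the identity floor;
* unique-unique — each read maps to exactly one contig among its best
  alignments; concordant iff both hit the same contig with opposite
  strands;
* multi-map — at least one read has best alignments on several contigs;
  concordant iff some contig is hit by both reads in opposite
  orientations.

"Best alignments" are all alignments within a small identity window of
the read's top identity (default 0.5%), because alignment tools emit
co-optimal hits and the multi-map category explicitly counts them.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

from .mapcov import BlockAlignment
from .varcall import round_half_up


@dataclass
class ConcordanceReport:
    """Pair-classification counts plus the two concordance percentages."""

    total_pairs: int
    both_mapped: int
    unique_unique: int
    unique_concordant: int
    multi: int
    multi_concordant: int
    unmapped: int

    @property
    def unique_pct(self) -> int | None:
        if self.unique_unique == 0:
            return None
        return round_half_up(100.0 * self.unique_concordant / self.unique_unique)

    @property
    def multi_pct(self) -> int | None:
        if self.multi == 0:
            return None
        return round_half_up(100.0 * self.multi_concordant / self.multi)

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "both_mapped": self.both_mapped,
            "unique_unique": self.unique_unique,
            "unique_concordant": self.unique_concordant,
            "unique_concordant_pct": self.unique_pct,
            "multi": self.multi,
            "multi_concordant": self.multi_concordant,
            "multi_concordant_pct": self.multi_pct,
            "unmapped": self.unmapped,
        }


def _best_set(
    alns: Sequence[BlockAlignment], min_identity: float, tie_window: float
) -> list[BlockAlignment]:
    pool = [a for a in alns if a.identity >= min_identity - 1e-12]
    if not pool:
        return []
    top = max(a.identity for a in pool)
    return [a for a in pool if a.identity >= top - tie_window]


def pair_concordance(
    alignments_by_read: Mapping[str, Sequence[BlockAlignment]],
    pairing: Mapping[str, str],
    min_identity: float = 0.90,
    tie_window: float = 0.005,
) -> ConcordanceReport:
    """Classify read pairs by mapping concordance.

    ``pairing`` maps forward read ids to reverse read ids.  Read ids in
    the pairing but absent from the alignments count as unmapped.  The
    identity floor is applied per alignment before classification.
    """
    total = len(pairing)
    both_mapped = uu = uu_conc = multi = multi_conc = unmapped = 0
    for fwd_id, rev_id in pairing.items():
        fwd = _best_set(alignments_by_read.get(fwd_id, ()), min_identity, tie_window)
        rev = _best_set(alignments_by_read.get(rev_id, ()), min_identity, tie_window)
        if not fwd or not rev:
            unmapped += 1
            continue
        both_mapped += 1
        fwd_contigs = {a.contig_id for a in fwd}
        rev_contigs = {a.contig_id for a in rev}
        concordant = any(
            f.contig_id == r.contig_id and f.strand != r.strand
            for f in fwd
            for r in rev
        )
        if len(fwd_contigs) == 1 and len(rev_contigs) == 1:
            uu += 1
            uu_conc += concordant
        else:
            multi += 1
            multi_conc += concordant
    return ConcordanceReport(
        total_pairs=total,
        both_mapped=both_mapped,
        unique_unique=uu,
        unique_concordant=uu_conc,
        multi=multi,
        multi_concordant=multi_conc,
        unmapped=unmapped,
    )


def write_report_json(report: ConcordanceReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_report_tsv(report: ConcordanceReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in report.to_dict().items():
            fh.write(f"{key}\t{value}\n")
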