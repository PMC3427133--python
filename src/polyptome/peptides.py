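"""GLW-amide neuropeptide-precursor scanning and pro-hormone processing.

Cnidarian GLW-amide neuropeptides end in glycine-leucine-tryptophan
amide; the amide group is donated by a glycine that follows the motif in
the precursor.  A precursor is recognised here as an open reading frame
containing several repeated GLW motifs, each classified by what follows
the core:

* ``G``  -> amidated (mature peptide ends GLW-NH2);
* ``CG`` -> cys-amidated (ends GLWC-NH2);
* ``C`` without a following G -> cys-unamidated (ends GLWC, no amide);
* anything else -> other.

Mature peptides are predicted by the classical processing grammar:
endoproteases cleave at the basic residues (K/R) flanking each motif;
dipeptidylaminopeptidases then iteratively remove X-Ala / X-Pro
dipeptides from the N-terminus; amidation consumes the terminal glycine;
an N-terminal glutamine can cyclise to pyroglutamate (pE).

Query peptides use the field's notation, e.g. ``pEPLPIGLW-NH2``: the
``pE`` prefix denotes a pyroglutamate derived from Q and the ``-NH2``
suffix the C-terminal amide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import FormatError
from .seqio import Contig, reverse_complement

logger = logging.getLogger(__name__)

_BASIC = frozenset("KR")
_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

AMIDATED = "amidated"
CYS_AMIDATED = "cys-amidated"
CYS_UNAMIDATED = "cys-unamidated"
OTHER = "other"


@dataclass(frozen=True)
class Orf:
    """A maximal stop-to-stop open reading frame on one of six frames.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    contig's plus strand; ``protein`` excludes any stop codon.
    """

    contig_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    start: int
    end: int
    protein: str


@dataclass(frozen=True)
class PrecursorHit:
    """An ORF with repeated GLW motifs and their amidation classes."""

    orf: Orf
    motif_positions: tuple[int, ...]  # protein indices of each 'GLW'
    motif_classes: tuple[str, ...]
    cpp_preceded: tuple[bool, ...]  # 'CPP' immediately before the motif

    @property
    def motif_count(self) -> int:
        return len(self.motif_positions)


@dataclass(frozen=True)
class MaturePeptide:
    """A predicted mature peptide after cleavage, trimming and amidation."""

    sequence: str
    n_terminal_pyroglu: bool
    c_terminal_amide: bool
    source_motif_index: int

    def notation(self) -> str:
        core = self.sequence
        if self.n_terminal_pyroglu and core.startswith("Q"):
            core = "pE" + core[1:]
        return core + ("-NH2" if self.c_terminal_amide else "")


def find_orfs(contig: Contig, min_aa: int = 60) -> list[Orf]:
    """All maximal stop-to-stop ORFs of length >= ``min_aa`` in six frames.

    Standard genetic code; ordering is deterministic (frame +1..+3 then
    -1..-3, then coordinate).  An ORF does not require an initiator
    codon: precursors are recognised by motif content, not by start
    selection.
    """
    L = contig.length
    orfs: list[Orf] = []
    for frame in (1, 2, 3, -1, -2, -3):
        seq = contig.seq if frame > 0 else reverse_complement(contig.seq)
        offset = abs(frame) - 1
        usable = (L - offset) // 3 * 3
        if usable < 3:
            continue
        protein = str(Seq(seq[offset : offset + usable]).translate())
        aa_start = 0
        for segment in protein.split("*"):
            if len(segment) >= min_aa:
                nt_start = offset + 3 * aa_start
                nt_end = nt_start + 3 * len(segment)
                if frame > 0:
                    start, end = nt_start, nt_end
                else:
                    start, end = L - nt_end, L - nt_start
                orfs.append(
                    Orf(
                        contig_id=contig.id,
                        frame=frame,
                        start=start,
                        end=end,
                        protein=segment,
                    )
                )
            aa_start += len(segment) + 1  # skip the stop
    return orfs


def _classify_motif(protein: str, pos: int) -> str:
    after = protein[pos + 3 : pos + 5]
    if after[:1] == "G":
        return AMIDATED
    if after == "CG":
        return CYS_AMIDATED
    if after[:1] == "C":
        return CYS_UNAMIDATED
    return OTHER


def scan_glw_precursors(
    orfs: Iterable[Orf], min_motifs: int = 3
) -> list[PrecursorHit]:
    """Report ORFs containing >= ``min_motifs`` GLW motifs, classified."""
    hits: list[PrecursorHit] = []
    for orf in orfs:
        positions = [m.start() for m in re.finditer("(?=GLW)", orf.protein)]
        if len(positions) < min_motifs:
            continue
        classes = tuple(_classify_motif(orf.protein, p) for p in positions)
        cpp = tuple(orf.protein[max(p - 3, 0) : p] == "CPP" for p in positions)
        hits.append(
            PrecursorHit(
                orf=orf,
                motif_positions=tuple(positions),
                motif_classes=classes,
                cpp_preceded=cpp,
            )
        )
    return hits


def _nearest_basic_upstream(protein: str, pos: int) -> int | None:
    for i in range(pos - 1, -1, -1):
        if protein[i] in _BASIC:
            return i
    return None


def _nearest_basic_downstream(protein: str, pos: int) -> int | None:
    for i in range(pos, len(protein)):
        if protein[i] in _BASIC:
            return i
    return None


def predict_mature_peptides(hit: PrecursorHit) -> list[MaturePeptide]:
    """Apply the processing grammar to every motif of a precursor hit.

    For each motif: cleave after the nearest upstream basic residue and
    before the nearest downstream one; iteratively trim X-A/X-P
    dipeptides from the N-terminus; remove the amide-donor glycine when
    the motif class provides one and it terminates the fragment; flag
    pyroglutamate when the processed peptide starts with Q.  Motifs with
    no flanking basic residue inside the ORF are skipped with a warning.
    """
    protein = hit.orf.protein
    peptides: list[MaturePeptide] = []
    for k, (pos, cls) in enumerate(zip(hit.motif_positions, hit.motif_classes)):
        core_end = pos + 3  # past 'GLW'
        if cls in (CYS_AMIDATED, CYS_UNAMIDATED):
            core_end += 1  # include the C
        donor = cls in (AMIDATED, CYS_AMIDATED)
        after_core = core_end + (1 if donor else 0)
        up = _nearest_basic_upstream(protein, pos)
        down = _nearest_basic_downstream(protein, after_core)
        if up is None or down is None:
            logger.warning(
                "motif %d of %s has no flanking basic residue; skipped",
                k,
                hit.orf.contig_id,
            )
            continue
        frag = protein[up + 1 : down]
        # Trim X-A/X-P dipeptides; an N-terminal Q stops trimming because
        # cyclisation to pyroglutamate blocks the aminopeptidase.
        while len(frag) >= 2 and frag[1] in ("A", "P") and not frag.startswith("Q"):
            frag = frag[2:]
        amide = False
        if donor and frag.endswith("G") and len(frag) > 1:
            frag = frag[:-1]
            amide = True
        if not frag:
            continue
        peptides.append(
            MaturePeptide(
                sequence=frag,
                n_terminal_pyroglu=frag.startswith("Q"),
                c_terminal_amide=amide,
                source_motif_index=k,
            )
        )
    return peptides


_QUERY_RE = re.compile(r"^(pE)?([A-Za-z]+?)(-?NH_?2_?)?$")


def parse_query_peptide(query: str) -> tuple[str, bool, bool]:
    """Parse ``pE...-NH2`` notation to (core, amidated, pyroglu_required).

    The ``pE`` prefix maps to a leading Q in the primary sequence.
    """
    m = _QUERY_RE.match(query.strip())
    if not m:
        raise FormatError(f"unparseable peptide query: {query!r}")
    pyro, body, amide = m.group(1), m.group(2).upper(), m.group(3)
    core = ("Q" + body) if pyro else body
    if not core or not set(core) <= _AA20:
        raise FormatError(f"query contains non-amino-acid characters: {query!r}")
    return core, amide is not None, pyro is not None


def match_query_peptide(
    peptides: Sequence[MaturePeptide], query: str
) -> list[tuple[MaturePeptide, str]]:
    """Match a query against predicted peptides.

    Exact matches require the same core sequence, the same amidation
    flag, and — when the query specifies pyroglutamate — a peptide that
    can form it (starts with Q).  C-terminal suffix matches (one core a
    proper suffix of the other, amidation equal) are reported separately
    as ``"suffix"``.
    """
    core, amide, pyro = parse_query_peptide(query)
    out: list[tuple[MaturePeptide, str]] = []
    for pep in peptides:
        if pep.c_terminal_amide != amide:
            continue
        if pep.sequence == core:
            if not pyro or pep.n_terminal_pyroglu:
                out.append((pep, "exact"))
            continue
        if pep.sequence.endswith(core) or core.endswith(pep.sequence):
            out.append((pep, "suffix"))
    return out


def scan_contigs(
    contigs: Iterable[Contig], min_motifs: int = 3, min_aa: int = 60
) -> list[PrecursorHit]:
    """Convenience: six-frame ORF scan plus precursor scan per contig."""
    hits: list[PrecursorHit] = []
    for contig in contigs:
        hits.extend(scan_glw_precursors(find_orfs(contig, min_aa), min_motifs))
    return hits
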