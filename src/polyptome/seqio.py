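"""Sequence containers and I/O for the formats the pipeline touches.

Only two dialects are supported, deliberately: multi-line FASTA (output
wrapped at 70 columns) and four-line Phred+33 FASTQ.  Nucleotide
sequences are restricted to the {A, C, G, T, N} alphabet because every
downstream consumer (pileups, hairpin scan, variant calling) assumes it;
other IUPAC ambiguity codes are rejected at the boundary rather than
silently propagated.

Parsing and serialisation are delegated to Bio.SeqIO; this module only
adds validation and the package's domain types.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FormatError

DNA_ALPHABET = frozenset("ACGTN")
MAX_QUALITY = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Byte-level code table: A=0, C=1, G=2, T=3, N=4; anything else = 255.
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODES[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _check_alphabet(seq: str) -> None:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise AlphabetError(f"unsupported sequence characters: {bad!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    codes = _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        _check_alphabet(seq)  # raises with a readable message
    return codes


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`."""
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True, slots=True)
class Contig:
    """A named assembled sequence (uppercase, {A,C,G,T,N})."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"contig {self.id!r} has an empty sequence")
        _check_alphabet(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class QualityRead:
    """A nucleotide read with per-base Phred quality scores.

    ``quals`` may be any integer sequence (list, tuple or numpy array) of
    the same length as ``bases``; values must lie in [0, 60].
    """

    id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        _check_alphabet(self.bases)
        if len(self.quals) > 0:
            if isinstance(self.quals, np.ndarray):
                lo, hi = int(self.quals.min()), int(self.quals.max())
            else:
                lo, hi = min(self.quals), max(self.quals)
            if lo < 0 or hi > MAX_QUALITY:
                raise FormatError(
                    f"read {self.id!r}: quality scores outside [0, {MAX_QUALITY}]"
                )

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a (possibly multi-line) FASTA file into Contigs, order preserved.

    Sequences are uppercased; an empty file or a file whose first
    non-blank line is not a header raises :class:`FormatError`.
    """
    with open(path) as handle:
        head = handle.read(1 << 16)
        stripped = head.lstrip()
        if not stripped:
            raise FormatError(f"{path}: empty FASTA file")
        if not stripped.startswith(">"):
            raise FormatError(f"{path}: does not start with a FASTA header")
        handle.seek(0)
        contigs = [
            Contig(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike) -> None:
    """Write contigs as FASTA wrapped at 70 columns."""
    records = (SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs)
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=70).write_file(records)


def read_fastq(path: str | os.PathLike) -> list[QualityRead]:
    """Read four-line Phred+33 FASTQ records.

    Raises :class:`FormatError` on truncated records or base/quality
    length mismatches (detected by the underlying parser).
    """
    try:
        return [
            QualityRead(
                rec.id,
                str(rec.seq).upper(),
                rec.letter_annotations["phred_quality"],
            )
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[QualityRead], path: str | os.PathLike) -> None:
    """Write reads as four-line Phred+33 FASTQ."""
    with open(path, "w") as handle:
        for read in reads:
            quals = "".join(chr(int(q) + 33) for q in read.quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{quals}\n")
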