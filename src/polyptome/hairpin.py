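"""Detection and repair of palindromic "hairpin" mis-assembled contigs.

A hairpin contig carries an arm and (approximately) the reverse
complement of that arm folded back at an apex, a known failure mode of
de Bruijn assemblers on palindromic or near-palindromic input.  The scan
here is un-gapped: for every candidate apex ``a`` it extends
anti-diagonally, comparing ``seq[a-1-j]`` with the complement of
``seq[a+j]``, and reports the apex supporting the longest arm whose
identity clears the threshold.  Repair splits the contig at the apex.

The original repair procedure published no algorithm or thresholds;
``min_arm`` and ``min_identity`` are therefore explicit parameters with
conservative defaults (100 bp arms at 95% identity), at which a random
1 kb sequence essentially never triggers a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .seqio import Contig, encode_bases


@dataclass(frozen=True)
class HairpinCall:
    """A detected fold: contig, 0-based apex, arm length and arm identity."""

    contig_id: str
    apex: int
    arm_length: int
    identity: float


def detect_hairpin(
    contig: Contig, min_arm: int = 100, min_identity: float = 0.95
) -> HairpinCall | None:
    """Scan for an inverted-repeat fold; return the best call or None.

    For each apex ``a`` the arm length ``m`` is the largest un-gapped
    anti-diagonal extension with identity >= ``min_identity`` and
    ``m >= min_arm`` (arms abut at the apex).  The call maximises arm
    length; ties break toward the lower apex coordinate.  Contigs
    shorter than ``2*min_arm`` return None.
    """
    L = contig.length
    if min_arm < 1:
        raise ParameterError("min_arm must be >= 1")
    if L < 2 * min_arm:
        return None
    x = encode_bases(contig.seq).astype(np.int16)
    comp = np.where(x < 4, 3 - x, np.int16(-1))  # N never matches

    m_max = L // 2
    cum = np.zeros(L + 1, dtype=np.int32)  # cum[a] = matches in arm of length m at apex a
    best_m = np.zeros(L + 1, dtype=np.int32)
    best_ident = np.zeros(L + 1, dtype=np.float64)
    for m in range(1, m_max + 1):
        j = m - 1
        # apexes a in [m, L-m]: compare x[a-1-j] with comp[a+j]
        hits = x[0 : L - 1 - 2 * j] == comp[2 * j + 1 : L]
        cum[m : L - m + 1] += hits
        if m < min_arm:
            continue
        window = cum[m : L - m + 1]
        ident = window / m
        good = ident >= min_identity - 1e-12
        if good.any():
            idx = np.flatnonzero(good) + m
            best_m[idx] = m
            best_ident[idx] = ident[good]
    if best_m.max() == 0:
        return None
    top = int(best_m.max())
    apex = int(np.flatnonzero(best_m == top)[0])  # lowest coordinate on ties
    return HairpinCall(
        contig_id=contig.id,
        apex=apex,
        arm_length=top,
        identity=float(best_ident[apex]),
    )


def split_hairpin(contig: Contig, call: HairpinCall) -> tuple[Contig, Contig]:
    """Split a hairpin contig at the apex into two contigs.

    Concatenating the two pieces reproduces the input exactly; ids are
    suffixed ``.a`` / ``.b``.
    """
    if not 0 < call.apex < contig.length:
        raise ParameterError(
            f"apex {call.apex} out of range for contig of length {contig.length}"
        )
    return (
        Contig(contig.id + ".a", contig.seq[: call.apex]),
        Contig(contig.id + ".b", contig.seq[call.apex :]),
    )


def repair_hairpins(
    contigs: list[Contig],
    min_arm: int = 100,
    min_identity: float = 0.95,
    min_len: int | None = 200,
) -> tuple[list[Contig], list[HairpinCall]]:
    """Detect and split hairpins across a contig set.

    Pieces shorter than ``min_len`` are dropped (the assembly's 200 bp
    floor, applied downstream of splitting); pass ``min_len=None`` to
    disable the floor.  Returns (repaired contigs, calls made).
    """
    out: list[Contig] = []
    calls: list[HairpinCall] = []
    for contig in contigs:
        call = detect_hairpin(contig, min_arm=min_arm, min_identity=min_identity)
        if call is None:
            out.append(contig)
            continue
        calls.append(call)
        for piece in split_hairpin(contig, call):
            if min_len is None or piece.length >= min_len:
                out.append(piece)
    return out, calls
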