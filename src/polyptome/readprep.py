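"""Duplicate-read collapsing and quality/length filtering.

The collapser groups reads (or read pairs) into "families" by an exact
prefix signature and emits one representative per family with a
per-position majority-consensus base and the maximum quality observed at
each position.  It is a declared simplification of full
amplification-duplicate correction: the contract is "one representative
read with improved quality scores per family", not a reimplementation of
any particular published collapser.

Trimming keeps, for each read, the longest contiguous window in which
every base has quality >= ``min_q`` and is not N (the leftmost window on
length ties) — the published constraint is on the *result* (no base
below Q10, no Ns), not on the procedure, and a longest-window rule is
the least destructive procedure that satisfies it.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import ParameterError
from .seqio import QualityRead

ReadOrPair = Union[QualityRead, tuple[QualityRead, QualityRead]]


@dataclass
class ReadFamily:
    """Reads sharing a prefix signature, plus their consensus representative."""

    key: tuple[str, ...]
    members: list[ReadOrPair]
    representative: ReadOrPair

    @property
    def size(self) -> int:
        return len(self.members)


def _consensus(reads: Sequence[QualityRead], rep_id: str) -> QualityRead:
    """Per-position majority base (ties: higher summed quality, then
    lexicographic); per-position quality = max over members."""
    if len(reads) == 1:
        r = reads[0]
        return QualityRead(rep_id, r.bases, list(r.quals))
    length = max(len(r) for r in reads)
    bases: list[str] = []
    quals: list[int] = []
    for pos in range(length):
        votes: dict[str, int] = {}
        qsum: dict[str, int] = {}
        qmax = 0
        for r in reads:
            if pos >= len(r):
                continue
            b = r.bases[pos]
            q = int(r.quals[pos])
            votes[b] = votes.get(b, 0) + 1
            qsum[b] = qsum.get(b, 0) + q
            qmax = max(qmax, q)
        best = min(votes, key=lambda b: (-votes[b], -qsum[b], b))
        bases.append(best)
        quals.append(qmax)
    return QualityRead(rep_id, "".join(bases), quals)


def collapse_duplicates(
    items: Sequence[ReadOrPair], prefix_len: int = 30
) -> tuple[list[ReadOrPair], dict[int, int]]:
    """Collapse duplicate reads (or pairs) into family representatives.

    Reads are grouped by the exact ``prefix_len``-mer prefix of each mate;
    each family yields one consensus representative.  Returns the
    representatives (in order of first family appearance) and a histogram
    of family sizes.  Idempotent: collapsing the representatives again is
    a no-op.
    """
    if prefix_len < 1:
        raise ParameterError(f"prefix_len must be >= 1, got {prefix_len}")
    families: "OrderedDict[tuple[str, ...], list[ReadOrPair]]" = OrderedDict()
    for item in items:
        mates = item if isinstance(item, tuple) else (item,)
        for m in mates:
            if prefix_len > len(m):
                raise ParameterError(
                    f"prefix_len {prefix_len} exceeds length of read {m.id!r}"
                )
        key = tuple(m.bases[:prefix_len] for m in mates)
        families.setdefault(key, []).append(item)

    representatives: list[ReadOrPair] = []
    histogram: dict[int, int] = {}
    for key, members in families.items():
        histogram[len(members)] = histogram.get(len(members), 0) + 1
        first = members[0]
        if isinstance(first, tuple):
            rep = tuple(
                _consensus([m[i] for m in members], first[i].id)  # type: ignore[index]
                for i in range(len(first))
            )
        else:
            rep = _consensus([m for m in members], first.id)  # type: ignore[misc]
        representatives.append(rep)  # type: ignore[arg-type]
    return representatives, histogram


def build_families(
    items: Sequence[ReadOrPair], prefix_len: int = 30
) -> list[ReadFamily]:
    """Like :func:`collapse_duplicates` but returning full family records."""
    if prefix_len < 1:
        raise ParameterError(f"prefix_len must be >= 1, got {prefix_len}")
    grouped: "OrderedDict[tuple[str, ...], list[ReadOrPair]]" = OrderedDict()
    for item in items:
        mates = item if isinstance(item, tuple) else (item,)
        key = tuple(m.bases[:prefix_len] for m in mates)
        grouped.setdefault(key, []).append(item)
    reps, _ = collapse_duplicates(items, prefix_len)
    return [
        ReadFamily(key=key, members=members, representative=rep)
        for (key, members), rep in zip(grouped.items(), reps)
    ]


def quality_trim(read: QualityRead, min_q: int = 10) -> QualityRead | None:
    """Longest contiguous window with every base >= ``min_q`` and not N.

    The boundary is inclusive (quality exactly ``min_q`` passes).  The
    leftmost window wins length ties.  Returns None when no base
    qualifies.
    """
    quals = np.asarray(read.quals)
    ok = quals >= min_q
    if "N" in read.bases:
        ok &= np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8) != ord("N")
    best_len = best_start = 0
    run_start = None
    for i, good in enumerate(ok):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if run_start is not None and len(ok) - run_start > best_len:
        best_len, best_start = len(ok) - run_start, run_start
    if best_len == 0:
        return None
    return QualityRead(
        read.id,
        read.bases[best_start : best_start + best_len],
        list(read.quals[best_start : best_start + best_len]),
    )


def length_filter(
    reads: Sequence[QualityRead | None], min_len: int = 45
) -> list[QualityRead]:
    """Keep reads with length >= ``min_len`` (inclusive), order preserved.

    None entries (reads emptied by trimming) are discarded.
    """
    return [r for r in reads if r is not None and len(r) >= min_len]
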