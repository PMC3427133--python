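"""Assembly summary statistics and length-binned rate tables.

N50 is defined as the largest length L such that contigs of length >= L
contain at least half of the assembly's total bases.  The length
histogram uses fixed 400 bp bins anchored at 200 bp, the assembly's
contig floor; the binned rate table partitions contigs into the
half-open ranges [200, 600), [600, 1000), [1000, 1400), [1400, inf) and
reports integer (half-up rounded) percentages of flagged contigs per
range, mirroring the layout used to report annotation success by length.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import StatsError
from .seqio import Contig
from .varcall import round_half_up

logger = logging.getLogger(__name__)

LengthLike = Union[Contig, int]


def _lengths(items: Iterable[LengthLike]) -> np.ndarray:
    return np.asarray(
        [it.length if isinstance(it, Contig) else int(it) for it in items],
        dtype=np.int64,
    )


@dataclass
class AssemblyStats:
    """Contig-set summary: count, totals, central tendencies, N50, histogram."""

    count: int
    total_bp: int
    min_len: int
    max_len: int
    mean: float
    median: float
    n50: int
    histogram: dict[int, int]  # bin start -> count; 400 bp bins from 200

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "total_bp": self.total_bp,
            "min_len": self.min_len,
            "max_len": self.max_len,
            "mean": self.mean,
            "median": self.median,
            "n50": self.n50,
            "histogram": {str(k): v for k, v in self.histogram.items()},
        }


def n50(lengths: Iterable[int]) -> int:
    """Largest L with sum(lengths >= L) >= total/2."""
    arr = np.sort(_lengths(lengths))[::-1]
    if arr.size == 0:
        raise StatsError("N50 undefined for an empty set")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def assembly_stats(
    contigs: Sequence[LengthLike], min_len: int | None = 200
) -> AssemblyStats:
    """Summary statistics after applying the contig length floor.

    ``min_len=None`` disables the floor.  The mean is unrounded; round
    only at report time.
    """
    lengths = _lengths(contigs)
    if min_len is not None:
        lengths = lengths[lengths >= min_len]
    if lengths.size == 0:
        raise StatsError("no contigs after applying the length floor")
    hist: dict[int, int] = {}
    for length in lengths:
        start = 200 + 400 * max((int(length) - 200) // 400, 0)
        hist[start] = hist.get(start, 0) + 1
    return AssemblyStats(
        count=int(lengths.size),
        total_bp=int(lengths.sum()),
        min_len=int(lengths.min()),
        max_len=int(lengths.max()),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        n50=n50(lengths),
        histogram=dict(sorted(hist.items())),
    )


@dataclass(frozen=True)
class BinRow:
    lo: int
    hi: int | None  # None = open-ended
    total: int
    flagged: int
    pct: int

    @property
    def label(self) -> str:
        return f"{self.lo}+" if self.hi is None else f"{self.lo}-{self.hi - 1}"


@dataclass
class BinnedRateTable:
    """Per-length-range totals, flagged counts and integer percentages."""

    rows: list[BinRow]
    underflow: BinRow | None = None

    def to_dict(self) -> dict:
        rows = [
            {
                "range": r.label,
                "total": r.total,
                "flagged": r.flagged,
                "pct": r.pct,
            }
            for r in self.rows
        ]
        out = {"rows": rows}
        if self.underflow is not None:
            out["underflow"] = {
                "total": self.underflow.total,
                "flagged": self.underflow.flagged,
                "pct": self.underflow.pct,
            }
        return out


def binned_rate_table(
    contigs: Sequence[LengthLike],
    flags: Sequence[bool],
    bin_edges: Sequence[int] = (200, 600, 1000, 1400),
) -> BinnedRateTable:
    """Partition contigs into half-open length bins and rate the flags.

    The last bin is open-ended.  Contigs below the first edge are
    collected in an underflow row and logged.  Percentages are rounded
    half-up to integers.
    """
    lengths = _lengths(contigs)
    if len(lengths) != len(flags):
        raise StatsError("flags must align one-to-one with contigs")
    edges = list(bin_edges)
    totals = [0] * len(edges)
    hits = [0] * len(edges)
    under_total = under_hits = 0
    for length, flag in zip(lengths, flags):
        if length < edges[0]:
            under_total += 1
            under_hits += bool(flag)
            continue
        idx = len(edges) - 1
        for i in range(len(edges) - 1):
            if edges[i] <= length < edges[i + 1]:
                idx = i
                break
        totals[idx] += 1
        hits[idx] += bool(flag)

    def pct(f: int, t: int) -> int:
        return round_half_up(100.0 * f / t) if t else 0

    rows = [
        BinRow(
            lo=edges[i],
            hi=edges[i + 1] if i + 1 < len(edges) else None,
            total=totals[i],
            flagged=hits[i],
            pct=pct(hits[i], totals[i]),
        )
        for i in range(len(edges))
    ]
    underflow = None
    if under_total:
        logger.warning("%d contigs below the first bin edge", under_total)
        underflow = BinRow(
            lo=0,
            hi=edges[0],
            total=under_total,
            flagged=under_hits,
            pct=pct(under_hits, under_total),
        )
    return BinnedRateTable(rows=rows, underflow=underflow)


def write_stats_json(stats: AssemblyStats, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
        fh.write("\n")


def write_stats_tsv(stats: AssemblyStats, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        d = stats.to_dict()
        hist = d.pop("histogram")
        for key, value in d.items():
            fh.write(f"{key}\t{value}\n")
        for start, count in hist.items():
            fh.write(f"bin_{start}\t{count}\n")
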