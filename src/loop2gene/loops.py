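"""Reading, validation, filtering and summary of chromatin loop calls.

Loops arrive as BEDPE-like text (two anchors, a paired-end-tag support count
and a loop-caller q-value, one file per cell line).  Coordinates are 0-based
half-open throughout (BED convention); readers accept a 1-based dialect via a
flag.  Only cis (same-chromosome) interactions are retained — trans rows are
dropped with a logged count.

Loop length ("span") is the distance between anchor midpoints, which makes it
independent of anchor width.  The default filter keeps loops spanning
5 kb–2 Mb (closed interval), supported by at least two unique paired-end tags
and with q-value strictly below 5%.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "LoopRecord",
    "LoopSummary",
    "LoopParseError",
    "read_loops",
    "write_loops",
    "loop_span",
    "filter_loops",
    "summarize_loops",
]


class LoopParseError(ValueError):
    """Raised for a malformed loop file row; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def midpoint(self) -> int:
        """Midpoint position, rounded down."""
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Whether ``pos`` lies inside the half-open interval."""
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """Distance from a point to the interval; 0 if the point is inside."""
        if self.contains(pos):
            return 0
        return min(abs(pos - (self.end - 1)), abs(self.start - pos))


@dataclass(frozen=True)
class LoopRecord:
    """One cis chromatin interaction.

    Anchors are canonically ordered so that ``anchor1.start <= anchor2.start``;
    the constructor swaps them if needed.  ``loop_id`` is an optional stable
    label (assigned by readers/generators) used when evidence is reported.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int
    q_value: float
    cell_line: str = ""
    loop_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                f"trans interaction: {self.anchor1.chrom} vs {self.anchor2.chrom}"
            )
        if self.pet_count < 0:
            raise ValueError("pet_count must be >= 0")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")
        if self.anchor1.start > self.anchor2.start:
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    def span(self) -> int:
        return loop_span(self)


def loop_span(loop: LoopRecord) -> int:
    """Loop length: absolute distance between anchor midpoints (floored)."""
    return abs(loop.anchor2.midpoint - loop.anchor1.midpoint)


@dataclass
class LoopSummary:
    """Per-file loop tallies mirroring the standard per-cell-line summary."""

    total: int
    short_loops: int  # span < short_threshold
    long_loops: int
    promoter_loops: int
    median_promoter_span: float | None
    short_threshold: int = 20_000
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.short_loops + self.long_loops != self.total:
            raise ValueError("short_loops + long_loops must equal total")
        if self.promoter_loops > self.total:
            raise ValueError("promoter_loops cannot exceed total")

    @property
    def short_pct(self) -> float:
        """Short-loop fraction as a percentage, 1 decimal place."""
        return round(100.0 * self.short_loops / self.total, 1) if self.total else 0.0

    @property
    def long_pct(self) -> float:
        return round(100.0 * self.long_loops / self.total, 1) if self.total else 0.0

    @property
    def promoter_pct(self) -> float:
        return round(100.0 * self.promoter_loops / self.total, 1) if self.total else 0.0


def _parse_row(fields: Sequence[str], lineno: int, cell_line: str,
               one_based: bool) -> LoopRecord:
    if len(fields) < 8:
        raise LoopParseError(
            f"line {lineno}: expected >= 8 tab-separated columns, got {len(fields)}"
        )
    try:
        c1, s1, e1, c2, s2, e2 = (
            fields[0], int(fields[1]), int(fields[2]),
            fields[3], int(fields[4]), int(fields[5]),
        )
        pet = int(fields[6])
        q = float(fields[7])
    except ValueError as exc:
        raise LoopParseError(f"line {lineno}: malformed field ({exc})") from None
    if one_based:
        s1 -= 1
        s2 -= 1
    try:
        a1 = GenomicInterval(c1, s1, e1)
        a2 = GenomicInterval(c2, s2, e2)
        return LoopRecord(a1, a2, pet, q, cell_line=cell_line)
    except ValueError as exc:
        raise LoopParseError(f"line {lineno}: {exc}") from None


def read_loops(path: str | Path, cell_line: str = "",
               one_based: bool = False) -> list[LoopRecord]:
    """Read a BEDPE-like loop file.

    Expects >= 8 tab-separated columns per data row
    (chrom1, start1, end1, chrom2, start2, end2, pet_count, q_value);
    lines starting with '#' are comments.  Trans (different-chromosome) rows
    are dropped; the dropped count is logged.  Malformed rows raise
    :class:`LoopParseError` naming the line number.
    """
    path = Path(path)
    records: list[LoopRecord] = []
    n_trans = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 8 and fields[0] != fields[3]:
                n_trans += 1
                continue
            rec = _parse_row(fields, lineno, cell_line, one_based)
            rec = LoopRecord(rec.anchor1, rec.anchor2, rec.pet_count, rec.q_value,
                             cell_line=cell_line,
                             loop_id=f"{cell_line or path.stem}:{len(records)}")
            records.append(rec)
    if n_trans:
        logger.info("dropped %d trans interaction(s) from %s", n_trans, path)
    return records


def write_loops(loops: Iterable[LoopRecord], path: str | Path,
                include_span: bool = True) -> None:
    """Write loops in the same BEDPE dialect, plus a span column by default."""
    path = Path(path)
    with path.open("w") as fh:
        header = "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tpet_count\tq_value"
        if include_span:
            header += "\tspan"
        fh.write(header + "\n")
        for lp in loops:
            row = (f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                   f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                   f"{lp.pet_count}\t{lp.q_value:g}")
            if include_span:
                row += f"\t{lp.span()}"
            fh.write(row + "\n")


def filter_loops(loops: Iterable[LoopRecord], min_span: int = 5_000,
                 max_span: int = 2_000_000, min_pets: int = 2,
                 max_q: float = 0.05) -> list[LoopRecord]:
    """Apply the standard loop-call filter.

    Retains loops with ``min_span <= span <= max_span`` (closed interval),
    ``pet_count >= min_pets`` and ``q_value < max_q`` (strict).  Order is
    preserved; the operation is idempotent.
    """
    if min_span <= 0 or max_span <= 0 or min_pets <= 0:
        raise ValueError("thresholds must be positive")
    if min_span >= max_span:
        raise ValueError("min_span must be < max_span")
    return [
        lp for lp in loops
        if min_span <= lp.span() <= max_span
        and lp.pet_count >= min_pets
        and lp.q_value < max_q
    ]


def summarize_loops(loops: Sequence[LoopRecord],
                    promoter_flags: Sequence[bool],
                    short_threshold: int = 20_000,
                    cell_line: str = "") -> LoopSummary:
    """Tally loops into short/long and promoter-associated classes.

    ``promoter_flags`` must align with ``loops``.  The median span is computed
    over promoter-flagged loops only (mean of the middle two for even counts);
    with no promoter loops the median is None and a warning is logged.
    """
    if len(loops) != len(promoter_flags):
        raise ValueError("promoter_flags must align with loops")
    spans = [lp.span() for lp in loops]
    short = sum(1 for s in spans if s < short_threshold)
    promoter_spans = [s for s, flag in zip(spans, promoter_flags) if flag]
    if promoter_spans:
        median_span: float | None = float(statistics.median(promoter_spans))
    else:
        median_span = None
        logger.warning("no promoter-associated loops; median span undefined")
    return LoopSummary(
        total=len(loops),
        short_loops=short,
        long_loops=len(loops) - short,
        promoter_loops=len(promoter_spans),
        median_promoter_span=median_span,
        short_threshold=short_threshold,
        cell_line=cell_line,
    )
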