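"""Target-gene calling: credible variants x promoter-associated loops.

A gene G is nominated for risk locus L in one of two evidence modes:

* ``distal_loop`` — some loop carries a promoter assignment to G on one
  anchor while a credible variant (CV) of L falls inside the *other* anchor
  (the classic enhancer-to-promoter configuration);
* ``promoter_cv`` — a CV of L falls inside an anchor that itself carries the
  promoter assignment to G (the variant sits in the looping promoter).

Calls are deduplicated per (gene, locus) with evidence accumulated across
loops; if any distal evidence exists the call's mode is ``distal_loop``.
CV-in-anchor membership uses half-open [start, end) intervals.  A locus label
is taken from the CV table (cytoband-style input), never re-derived from
coordinates.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .annotate import PromoterAssignment
from .loops import LoopRecord

__all__ = [
    "CredibleVariant",
    "TargetGeneCall",
    "LocusSummary",
    "GlobalLocusStats",
    "read_credible_variants",
    "call_target_genes",
    "integrate_cell_lines",
    "locus_statistics",
]


@dataclass(frozen=True)
class CredibleVariant:
    """A GWAS credible variant: lead variant or correlated set member."""

    rsid: str
    chrom: str
    pos: int
    locus: str
    is_lead: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not self.locus:
            raise ValueError("locus label must be non-empty")


@dataclass
class TargetGeneCall:
    """A (gene, locus) nomination with accumulated looping evidence."""

    gene_id: str
    locus: str
    mode: str  # "distal_loop" | "promoter_cv"
    cell_lines: set[str] = field(default_factory=set)
    supporting_loops: list[str] = field(default_factory=list)
    is_nearest: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("distal_loop", "promoter_cv"):
            raise ValueError(f"unknown evidence mode {self.mode!r}")

    @property
    def multi_line(self) -> bool:
        """Supported by looping data from at least two cell lines."""
        return len(self.cell_lines) >= 2


@dataclass
class LocusSummary:
    locus: str
    n_target_genes: int
    nearest_overlap: int
    genes: list[str]

    def __post_init__(self) -> None:
        if self.nearest_overlap > self.n_target_genes:
            raise ValueError("nearest_overlap cannot exceed n_target_genes")


@dataclass
class GlobalLocusStats:
    """Cross-locus statistics over integrated target-gene calls."""

    n_loci: int                    # loci with >= 1 call
    n_target_genes: int            # distinct genes called anywhere
    per_locus_counts: dict[str, int]
    min_per_locus: int | None
    max_per_locus: int | None
    median_per_locus: float | None  # over loci with >= 1 call
    nearest_overlap: int            # called genes in any locus's nearest set
    skipped_pct: float              # 100 * (1 - overlap / n_target_genes), rounded


def read_credible_variants(path: str | Path) -> list[CredibleVariant]:
    """Read a CV table: TSV with columns rsid, chrom, pos, locus, is_lead."""
    path = Path(path)
    cvs: list[CredibleVariant] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "rsid":  # header
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}, line {lineno}: expected 5 columns")
            cvs.append(CredibleVariant(
                rsid=fields[0], chrom=fields[1], pos=int(fields[2]),
                locus=fields[3],
                is_lead=fields[4].strip().lower() in ("1", "true", "yes")))
    return cvs


def _anchor_tree(loops: Sequence[LoopRecord]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over all anchors, data = (loop idx, anchor idx)."""
    trees: dict[str, IntervalTree] = {}
    for li, loop in enumerate(loops):
        for ai, anchor in ((1, loop.anchor1), (2, loop.anchor2)):
            trees.setdefault(anchor.chrom, IntervalTree()).addi(
                anchor.start, anchor.end, (li, ai))
    return trees


def call_target_genes(assignments: Sequence[PromoterAssignment],
                      loops: Sequence[LoopRecord],
                      cvs: Sequence[CredibleVariant]) -> list[TargetGeneCall]:
    """Intersect CVs with promoter-associated loops to nominate target genes.

    ``assignments`` must index into ``loops`` (typically the filtered set the
    classification ran on).  CVs overlapping no anchor contribute nothing.
    Returns one call per (gene, locus), sorted by (locus, gene).
    """
    trees = _anchor_tree(loops)
    # (loop idx, anchor idx) -> CVs inside that anchor
    anchor_cvs: dict[tuple[int, int], list[CredibleVariant]] = {}
    for cv in cvs:
        tree = trees.get(cv.chrom)
        if tree is None:
            continue
        for iv in tree.at(cv.pos):
            anchor_cvs.setdefault(iv.data, []).append(cv)

    calls: dict[tuple[str, str], TargetGeneCall] = {}

    def _record(gene_id: str, cv: CredibleVariant, loop: LoopRecord,
                loop_index: int, distal: bool) -> None:
        key = (gene_id, cv.locus)
        call = calls.get(key)
        if call is None:
            call = TargetGeneCall(gene_id=gene_id, locus=cv.locus,
                                  mode="promoter_cv")
            calls[key] = call
        if distal:
            call.mode = "distal_loop"
        loop_label = loop.loop_id or str(loop_index)
        if loop_label not in call.supporting_loops:
            call.supporting_loops.append(loop_label)
        if loop.cell_line:
            call.cell_lines.add(loop.cell_line)

    for asg in assignments:
        loop = loops[asg.loop_index]
        other = 2 if asg.anchor_index == 1 else 1
        for cv in anchor_cvs.get((asg.loop_index, other), ()):  # distal evidence
            _record(asg.gene_id, cv, loop, asg.loop_index, distal=True)
        for cv in anchor_cvs.get((asg.loop_index, asg.anchor_index), ()):
            _record(asg.gene_id, cv, loop, asg.loop_index, distal=False)

    return [calls[key] for key in sorted(calls, key=lambda k: (k[1], k[0]))]


def integrate_cell_lines(
        per_line_calls: Mapping[str, Sequence[TargetGeneCall]]
) -> list[TargetGeneCall]:
    """Union target-gene calls across cell lines.

    Evidence (cell lines, supporting loops) accumulates per (gene, locus);
    a call's mode becomes ``distal_loop`` if any contributing line had distal
    evidence.  Multi-line support is exposed as ``TargetGeneCall.multi_line``.
    """
    merged: dict[tuple[str, str], TargetGeneCall] = {}
    for line, line_calls in per_line_calls.items():
        for call in line_calls:
            key = (call.gene_id, call.locus)
            tgt = merged.get(key)
            if tgt is None:
                tgt = TargetGeneCall(gene_id=call.gene_id, locus=call.locus,
                                     mode=call.mode)
                merged[key] = tgt
            if call.mode == "distal_loop":
                tgt.mode = "distal_loop"
            tgt.cell_lines.update(call.cell_lines or {line})
            for lid in call.supporting_loops:
                if lid not in tgt.supporting_loops:
                    tgt.supporting_loops.append(lid)
            tgt.is_nearest = tgt.is_nearest or call.is_nearest
    return [merged[key] for key in sorted(merged, key=lambda k: (k[1], k[0]))]


def locus_statistics(calls: Sequence[TargetGeneCall],
                     nearest_map: Mapping[str, set[str]]
                     ) -> tuple[list[LocusSummary], GlobalLocusStats]:
    """Per-locus and global statistics over integrated calls.

    ``nearest_map`` maps each locus to the union of nearest-gene sets of its
    CVs.  The per-locus median counts only loci with >= 1 call; the global
    nearest overlap counts distinct called genes that appear in *any* locus's
    nearest set; the skipped fraction is its complement as a rounded
    percentage.  Calls' ``is_nearest`` flags are set in place.
    """
    per_locus: dict[str, list[TargetGeneCall]] = {}
    for call in calls:
        per_locus.setdefault(call.locus, []).append(call)

    all_nearest: set[str] = set()
    for nset in nearest_map.values():
        all_nearest.update(nset)

    summaries: list[LocusSummary] = []
    for locus in sorted(per_locus):
        locus_calls = per_locus[locus]
        genes = sorted({c.gene_id for c in locus_calls})
        locus_nearest = nearest_map.get(locus, set())
        for c in locus_calls:
            c.is_nearest = c.gene_id in locus_nearest
        summaries.append(LocusSummary(
            locus=locus, n_target_genes=len(genes),
            nearest_overlap=len(set(genes) & locus_nearest), genes=genes))

    all_genes = sorted({c.gene_id for c in calls})
    counts = {s.locus: s.n_target_genes for s in summaries}
    nonzero = [n for n in counts.values() if n > 0]
    overlap = len(set(all_genes) & all_nearest)
    skipped = (round(100.0 * (1 - overlap / len(all_genes)))
               if all_genes else 0.0)
    stats = GlobalLocusStats(
        n_loci=len(nonzero),
        n_target_genes=len(all_genes),
        per_locus_counts=counts,
        min_per_locus=min(nonzero) if nonzero else None,
        max_per_locus=max(nonzero) if nonzero else None,
        median_per_locus=float(statistics.median(nonzero)) if nonzero else None,
        nearest_overlap=overlap,
        skipped_pct=float(skipped),
    )
    return summaries, stats
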