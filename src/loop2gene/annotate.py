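"""Gene models, strand-aware TSSs, promoter-anchor classification, nearest genes.

A loop anchor is *promoter-associated* when it lies within a flank (default
3 kb, inclusive, point-to-interval distance) of a transcription start site.
TSSs are taken per transcript, so multi-promoter genes qualify via any of
their TSSs; divergent antisense pairs that share a promoter region can both
be assigned to the same anchor.

The nearest-gene metric for a variant is distance to the nearest TSS (not the
gene body); all genes attaining the minimum are returned, so ties yield sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .loops import GenomicInterval, LoopRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PromoterAssignment",
    "read_gene_models",
    "anchor_distance_to_tss",
    "classify_promoter_loops",
    "nearest_genes",
    "locus_nearest_map",
]

#: recognised biotype buckets
BIOTYPES = ("coding", "noncoding", "antisense", "miRNA", "other")

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncrna": "noncoding",
    "lincrna": "noncoding",
    "noncoding": "noncoding",
    "non_coding": "noncoding",
    "antisense": "antisense",
    "antisense_rna": "antisense",
    "mirna": "miRNA",
}


def _bucket_biotype(raw: str | None) -> str:
    if raw is None:
        return "other"
    return _BIOTYPE_MAP.get(raw.lower(), "other")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-aware transcript TSS positions (0-based)."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    tss_list: tuple[int, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id} has no TSS")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype bucket {self.biotype!r}")


@dataclass(frozen=True)
class PromoterAssignment:
    """A (loop anchor, gene) promoter association.

    ``loop_index`` indexes the loop list the classification ran on;
    ``anchor_index`` is 1 or 2; ``tss`` is the nearest qualifying TSS and
    ``distance`` its point-to-interval distance (<= the flank used).
    """

    loop_index: int
    anchor_index: int
    gene_id: str
    tss: int
    distance: int

    def __post_init__(self) -> None:
        if self.anchor_index not in (1, 2):
            raise ValueError("anchor_index must be 1 or 2")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _tss_from_interval(start0: int, end0_exclusive: int, strand: str) -> int:
    """TSS of a 0-based half-open transcript interval: start on '+', last base on '-'."""
    return start0 if strand == "+" else end0_exclusive - 1


def _read_bed6(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}, line {lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}, line {lineno}: missing/invalid strand")
            tss = _tss_from_interval(int(start), int(end), strand)
            entry = genes.setdefault(name, {
                "chrom": chrom, "strand": strand, "tss": set(), "biotype": "other",
            })
            if entry["chrom"] != chrom or entry["strand"] != strand:
                raise ValueError(f"gene {name}: inconsistent chrom/strand across rows")
            entry["tss"].add(tss)
    return [
        GeneModel(gene_id=name, name=name, chrom=e["chrom"], strand=e["strand"],
                  tss_list=tuple(sorted(e["tss"])), biotype=e["biotype"])
        for name, e in genes.items()
    ]


def _read_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    feature_types = set(db.featuretypes())
    tx_type = "transcript" if "transcript" in feature_types else (
        "mRNA" if "mRNA" in feature_types else "gene")
    genes: dict[str, dict] = {}
    for feat in db.features_of_type(tx_type):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"feature {feat.id}: missing strand")
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        name = feat.attributes.get("gene_name", [gene_id])[0]
        raw_biotype = None
        for key in ("gene_biotype", "gene_type", "transcript_biotype"):
            if key in feat.attributes:
                raw_biotype = feat.attributes[key][0]
                break
        # gffutils exposes 1-based inclusive coordinates; convert to 0-based.
        tss = _tss_from_interval(feat.start - 1, feat.end, feat.strand)
        entry = genes.setdefault(gene_id, {
            "name": name, "chrom": feat.seqid, "strand": feat.strand,
            "tss": set(), "biotype": _bucket_biotype(raw_biotype),
        })
        entry["tss"].add(tss)
    return [
        GeneModel(gene_id=gid, name=e["name"], chrom=e["chrom"], strand=e["strand"],
                  tss_list=tuple(sorted(e["tss"])), biotype=e["biotype"])
        for gid, e in genes.items()
    ]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF/GFF (gene/transcript features) or BED6 file.

    The TSS is the 0-based feature start on the '+' strand and the last base
    (feature end - 1) on the '-' strand, one per transcript, deduplicated per
    gene.  Unknown biotypes map to 'other'; a missing strand is an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path)
    return _read_bed6(path)


def anchor_distance_to_tss(anchor: GenomicInterval, tss: int,
                           chrom: str | None = None) -> int:
    """Point-to-interval distance from a TSS to an anchor (0 if contained)."""
    if chrom is not None and chrom != anchor.chrom:
        raise ValueError(f"TSS chromosome {chrom} != anchor chromosome {anchor.chrom}")
    return anchor.distance_to(tss)


class _TssIndex:
    """Sorted per-chromosome TSS arrays for window and nearest queries."""

    def __init__(self, genes: list[GeneModel]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        self.genes = genes
        for gi, gene in enumerate(genes):
            for tss in gene.tss_list:
                per_chrom.setdefault(gene.chrom, []).append((tss, gi))
        self.positions: dict[str, np.ndarray] = {}
        self.gene_idx: dict[str, np.ndarray] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            self.positions[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self.gene_idx[chrom] = np.array([g for _, g in pairs], dtype=np.int64)

    def window(self, chrom: str, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """All (tss, gene index) with lo <= tss <= hi."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return pos[i:j], self.gene_idx[chrom][i:j]


def classify_promoter_loops(loops: list[LoopRecord], genes: list[GeneModel],
                            flank: int = 3_000) -> list[PromoterAssignment]:
    """Find all promoter-associated anchors among ``loops``.

    Emits one assignment per (loop, anchor, gene) whose nearest qualifying TSS
    lies within ``flank`` bp (inclusive, point-to-interval distance) of the
    anchor.  A loop may qualify at both anchors; several genes (e.g. a
    divergent coding/antisense pair sharing a promoter) may share one anchor.
    """
    index = _TssIndex(genes)
    assignments: list[PromoterAssignment] = []
    for li, loop in enumerate(loops):
        for ai, anchor in ((1, loop.anchor1), (2, loop.anchor2)):
            tss_pos, gidx = index.window(anchor.chrom,
                                         anchor.start - flank,
                                         anchor.end - 1 + flank)
            best: dict[int, tuple[int, int]] = {}  # gene idx -> (distance, tss)
            for tss, gi in zip(tss_pos.tolist(), gidx.tolist()):
                d = anchor.distance_to(tss)
                if d <= flank and (gi not in best or (d, tss) < best[gi]):
                    best[gi] = (d, tss)
            for gi, (d, tss) in sorted(best.items()):
                assignments.append(PromoterAssignment(
                    loop_index=li, anchor_index=ai,
                    gene_id=genes[gi].gene_id, tss=tss, distance=d))
    return assignments


def nearest_genes(genes: list[GeneModel], chrom: str, pos: int) -> set[str]:
    """All gene ids attaining the minimum TSS distance to a variant position.

    Ties are returned as a set.  With no genes on the chromosome the result
    is empty and a warning is logged.
    """
    best_d: int | None = None
    winners: set[str] = set()
    for gene in genes:
        if gene.chrom != chrom:
            continue
        d = min(abs(pos - tss) for tss in gene.tss_list)
        if best_d is None or d < best_d:
            best_d, winners = d, {gene.gene_id}
        elif d == best_d:
            winners.add(gene.gene_id)
    if best_d is None:
        logger.warning("no genes on chromosome %s; nearest-gene set empty", chrom)
    return winners


def locus_nearest_map(cvs, genes: list[GeneModel]) -> dict[str, set[str]]:
    """Per-locus nearest-gene sets: the union over that locus's credible variants."""
    out: dict[str, set[str]] = {}
    for cv in cvs:
        out.setdefault(cv.locus, set()).update(nearest_genes(genes, cv.chrom, cv.pos))
    return out
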