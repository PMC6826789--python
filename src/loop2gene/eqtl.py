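"""eQTL / credible-variant overlap.

For each target gene, the "top eQTLs" are the variants attaining the gene's
minimum association p-value (exact ties included); a ranked top-K mode is
also available.  A gene is flagged when its top set contains a GWAS credible
variant — evidence that risk variation associates with its expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .targets import CredibleVariant

__all__ = [
    "EqtlRecord",
    "TopEqtlSet",
    "read_eqtl_table",
    "top_eqtls",
    "overlap_cvs",
]


@dataclass(frozen=True)
class EqtlRecord:
    gene_id: str
    variant: str
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class TopEqtlSet:
    """The variant(s) attaining a gene's minimum eQTL p-value."""

    gene_id: str
    variants: frozenset[str]
    min_p: float

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("top set must be non-empty")


def read_eqtl_table(path: str | Path) -> list[EqtlRecord]:
    """Read an eQTL TSV with columns gene, variant, p_value (header optional)."""
    records: list[EqtlRecord] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("gene", "gene_id"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 columns")
            records.append(EqtlRecord(fields[0], fields[1], float(fields[2])))
    return records


def top_eqtls(records: Sequence[EqtlRecord], top_k: int | None = None
              ) -> list[TopEqtlSet]:
    """Per-gene top eQTL sets.

    Default: the exact minimum-p tie set.  With ``top_k``, the variants with
    the K smallest p-values per gene (ties at the Kth rank included) —
    ``min_p`` still reports the gene's minimum.
    """
    per_gene: dict[str, list[EqtlRecord]] = {}
    for rec in records:
        per_gene.setdefault(rec.gene_id, []).append(rec)
    out: list[TopEqtlSet] = []
    for gene in sorted(per_gene):
        recs = sorted(per_gene[gene], key=lambda r: (r.p_value, r.variant))
        min_p = recs[0].p_value
        if top_k is None:
            chosen = [r.variant for r in recs if r.p_value == min_p]
        else:
            cutoff = recs[min(top_k, len(recs)) - 1].p_value
            chosen = [r.variant for r in recs if r.p_value <= cutoff]
        out.append(TopEqtlSet(gene, frozenset(chosen), min_p))
    return out


def overlap_cvs(tops: Iterable[TopEqtlSet], cvs: Sequence[CredibleVariant],
                target_genes: set[str]) -> list[tuple[str, str, str]]:
    """(gene, variant, locus) triples where a target gene's top eQTL set
    contains a credible variant.  Genes outside ``target_genes`` are ignored."""
    cv_locus = {cv.rsid: cv.locus for cv in cvs}
    hits: list[tuple[str, str, str]] = []
    for top in tops:
        if top.gene_id not in target_genes:
            continue
        for variant in sorted(top.variants):
            if variant in cv_locus:
                hits.append((top.gene_id, variant, cv_locus[variant]))
    return sorted(hits)
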