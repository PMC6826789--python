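"""Synthetic inputs with planted ground truth, plus packaged table fixtures.

The generator emits every input the pipeline consumes — a gene annotation
with strand-aware TSSs (including divergent antisense pairs sharing a
promoter region), per-cell-line loop files with distance-decaying PET
support, credible-variant tables with planted anchor overlaps, an LD panel /
annotation / summary-statistic trio with a known heritability enrichment,
and eQTL tables with known top variants — while recording exactly which
(gene, locus, mode) calls it planted.

Placement is collision-free by construction (decoy variants are rejected
from all anchors; decoy loops that would touch a planted variant through a
promoter are discarded), so pipeline recovery of the planted calls is exact:
target calling is deterministic interval logic, and any discrepancy is a
defect, not noise.  Fixtures transcribe the published tables verbatim,
including the FDR = 0.05 boundary row and the 102 listed target genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from . import ldsc as ldsc_mod
from .annotate import GeneModel, _TssIndex
from .enrich import ScoredRecord
from .loops import GenomicInterval, LoopRecord, write_loops
from .targets import CredibleVariant

__all__ = [
    "SimConfig",
    "LdscSimConfig",
    "EqtlSimConfig",
    "GroundTruth",
    "generate_genome",
    "write_genome_gtf",
    "generate_loops_and_cvs",
    "generate_ldsc_inputs",
    "generate_eqtl",
    "write_simulation",
    "load_fixture",
]

_ANCHOR_HALF = 2_500
_PROMOTER_FLANK = 3_000


@dataclass
class LdscSimConfig:
    """Heritability-simulation block: desk-scale panel and GWAS sizes."""

    n_snps: int = 10_000
    n_individuals: int = 500      # LD reference panel, 1000G-EUR scale
    n_gwas: int = 5_000
    h2: float = 0.5
    enrichment_true: float = 5.0
    target_fraction: float = 0.05


@dataclass
class EqtlSimConfig:
    n_genes: int = 30
    variants_per_gene: int = 20
    cv_top_fraction: float = 0.1  # genes whose top eQTL is planted as a CV


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic pipeline inputs.

    16 risk loci with ~29 credible variants each (~460 total), 13 of them
    (fraction 0.8125) carrying planted target genes, four cell lines, and
    log-normal loop spans with median ~200 kb so promoter-associated loops
    reproduce the long-range scale of real promoter interactions.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 30_000_000
    n_genes: int = 120
    antisense_pair_fraction: float = 0.1
    n_loci: int = 16
    cvs_per_locus: int = 29
    n_loops: int = 600            # per cell line, before filtering
    pet_decay_exponent: float = 1.0
    planted_target_fraction: float = 0.8125
    promoter_cv_fraction: float = 0.05
    multi_line_fraction: float = 0.36
    span_log_median: float = math.log(200_000.0)
    span_log_sigma: float = 0.8
    cell_lines: tuple[str, ...] = ("simA", "simB", "simC", "simD")
    ldsc: LdscSimConfig = field(default_factory=LdscSimConfig)
    eqtl: EqtlSimConfig = field(default_factory=EqtlSimConfig)

    def __post_init__(self) -> None:
        if isinstance(self.ldsc, dict):
            self.ldsc = LdscSimConfig(**self.ldsc)
        if isinstance(self.eqtl, dict):
            self.eqtl = EqtlSimConfig(**self.eqtl)
        self.cell_lines = tuple(self.cell_lines)
        for name in ("n_chromosomes", "n_genes", "n_loci", "cvs_per_locus",
                     "n_loops"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("antisense_pair_fraction", "planted_target_fraction",
                     "promoter_cv_fraction", "multi_line_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for exact-recovery checks."""

    planted_calls: list[dict]            # {gene, locus, mode, cell_lines}
    true_enrichment: float
    top_eqtls: dict[str, list[str]]
    eqtl_cv_genes: list[str]

    def call_set(self) -> set[tuple[str, str, str]]:
        return {(c["gene"], c["locus"], c["mode"]) for c in self.planted_calls}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome

def generate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Generate gene models with strand-aware TSSs.

    A configured fraction of genes receive a divergent antisense partner
    whose TSS lies within 3 kb on the opposite strand, emulating shared
    promoter regions.  Raises if the gene density does not fit the
    chromosomes.
    """
    rng = rng or np.random.default_rng(config.seed)
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    usable = config.chrom_length - 4_000_000  # margins for distal anchors
    spacing = usable // per_chrom
    if spacing < 10_000:
        raise ValueError("infeasible gene density: genes would overlap "
                         "beyond the chromosome")
    genes: list[GeneModel] = []
    n_pairs = round(config.antisense_pair_fraction * config.n_genes)
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        rank = i // config.n_chromosomes
        tss = 2_000_000 + rank * spacing + int(rng.integers(0, spacing // 4))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_list = [tss]
        if rng.random() < 0.3:  # second transcript promoter
            tss_list.append(tss + int(rng.integers(4_000, 8_000))
                            * (1 if strand == "+" else -1))
        genes.append(GeneModel(
            gene_id=f"G{i:04d}", name=f"G{i:04d}", chrom=chrom, strand=strand,
            tss_list=tuple(sorted(tss_list)), biotype="coding"))
        if i < n_pairs:
            gap = int(rng.integers(500, 2_800))
            partner_strand = "-" if strand == "+" else "+"
            genes.append(GeneModel(
                gene_id=f"G{i:04d}-AS", name=f"G{i:04d}-AS", chrom=chrom,
                strand=partner_strand,
                tss_list=(tss + gap,), biotype="antisense"))
    return genes


def write_genome_gtf(genes: list[GeneModel], path: str | Path,
                     tx_length: int = 2_000) -> None:
    """Write gene models as GTF, one transcript per TSS (1-based, inclusive)."""
    biotype_out = {"coding": "protein_coding", "noncoding": "lncRNA",
                   "antisense": "antisense", "miRNA": "miRNA", "other": "misc_RNA"}
    with Path(path).open("w") as fh:
        for gene in genes:
            for t, tss in enumerate(gene.tss_list):
                if gene.strand == "+":
                    start1, end1 = tss + 1, tss + tx_length
                else:
                    start1, end1 = max(1, tss + 2 - tx_length), tss + 1
                attrs = (f'gene_id "{gene.gene_id}"; '
                         f'transcript_id "{gene.gene_id}.t{t + 1}"; '
                         f'gene_name "{gene.name}"; '
                         f'gene_biotype "{biotype_out[gene.biotype]}";')
                fh.write(f"{gene.chrom}\tsim\ttranscript\t{start1}\t{end1}"
                         f"\t.\t{gene.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# loops and credible variants

def _draw_span(config: SimConfig, rng: np.random.Generator) -> int:
    s = math.exp(rng.normal(config.span_log_median, config.span_log_sigma))
    return int(min(max(s, 8_000), 1_900_000))


def _pet_count(span: int, config: SimConfig, rng: np.random.Generator) -> int:
    lam = 2.0 + 20.0 * (5_000.0 / span) ** config.pet_decay_exponent
    return int(rng.poisson(lam))


class _AnchorRegistry:
    """All anchors placed so far, for overlap / containment rejection."""

    def __init__(self) -> None:
        self.trees: dict[str, IntervalTree] = {}

    def add(self, iv: GenomicInterval) -> None:
        self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.at(pos))


def _genes_within_flank(index: _TssIndex, genes: list[GeneModel],
                        anchor: GenomicInterval) -> list[str]:
    tss_pos, gidx = index.window(anchor.chrom,
                                 anchor.start - _PROMOTER_FLANK,
                                 anchor.end - 1 + _PROMOTER_FLANK)
    hit = {int(gi) for tss, gi in zip(tss_pos, gidx)
           if anchor.distance_to(int(tss)) <= _PROMOTER_FLANK}
    return sorted(genes[gi].gene_id for gi in hit)


def generate_loops_and_cvs(
        config: SimConfig, genes: list[GeneModel],
        rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[LoopRecord]], list[CredibleVariant], GroundTruth]:
    """Generate per-cell-line loop calls, a CV table and the planted truth.

    For each planted locus, loops are anchored at target-gene promoters with
    the partner anchor placed away from all TSSs; the locus CV sits inside
    the distal anchor (``distal_loop`` mode) or inside the promoter anchor
    itself (``promoter_cv`` mode).  Remaining loops and CVs are decoys:
    decoy CVs never fall inside any anchor, and decoy loops that would link
    a planted CV to a promoter are discarded, so the planted call set is
    exactly what the pipeline should recover.
    """
    rng = rng or np.random.default_rng(config.seed)
    index = _TssIndex(genes)
    registry = _AnchorRegistry()
    n_planted_loci = round(config.planted_target_fraction * config.n_loci)
    loci = [f"locus_{i + 1:02d}" for i in range(config.n_loci)]
    chrom_of_gene = {g.gene_id: g.chrom for g in genes}

    planted: list[dict] = []
    planted_loops: list[tuple[LoopRecord, list[str]]] = []  # (loop, lines)
    cvs: list[CredibleVariant] = []
    planted_cv_positions: list[tuple[str, int]] = []

    gene_pool = [g for g in genes if not g.gene_id.endswith("-AS")]
    rng.shuffle(gene_pool)
    pool_iter = iter(gene_pool)

    for locus_i in range(n_planted_loci):
        locus = loci[locus_i]
        n_targets = 1 + int(rng.poisson(2.5))
        locus_chrom: str | None = None
        for _ in range(n_targets):
            gene = next(pool_iter, None)
            if gene is None:
                break
            if locus_chrom is None:
                locus_chrom = gene.chrom
            elif gene.chrom != locus_chrom:
                continue  # keep a locus on one chromosome
            tss = gene.tss_list[0]
            promoter = GenomicInterval(gene.chrom, tss - 2_000, tss + 3_000)
            mode = ("promoter_cv"
                    if rng.random() < config.promoter_cv_fraction
                    else "distal_loop")
            if mode == "promoter_cv" and registry.overlaps(
                    promoter.chrom, promoter.start, promoter.end):
                mode = "distal_loop"
            distal = None
            for _attempt in range(60):
                span = _draw_span(config, rng)
                direction = 1 if rng.random() < 0.5 else -1
                mid = promoter.midpoint + direction * span
                start = mid - _ANCHOR_HALF
                if start < 0 or mid + _ANCHOR_HALF > config.chrom_length:
                    continue
                cand = GenomicInterval(gene.chrom, start, mid + _ANCHOR_HALF)
                if registry.overlaps(cand.chrom, cand.start - _PROMOTER_FLANK,
                                     cand.end + _PROMOTER_FLANK):
                    continue
                if _genes_within_flank(index, genes, cand):
                    continue  # distal anchor must not be promoter-proximal
                distal = cand
                break
            if distal is None:
                continue
            registry.add(promoter)
            registry.add(distal)
            loop = LoopRecord(promoter, distal,
                              pet_count=max(2, _pet_count(loop_span_hint := max(
                                  abs(distal.midpoint - promoter.midpoint), 5_000),
                                  config, rng)),
                              q_value=float(rng.uniform(1e-5, 0.01)))
            n_lines = (int(rng.integers(2, len(config.cell_lines) + 1))
                       if rng.random() < config.multi_line_fraction else 1)
            lines = list(rng.choice(config.cell_lines, size=n_lines,
                                    replace=False))
            planted_loops.append((loop, lines))
            if mode == "promoter_cv":
                cv_pos = tss + int(rng.integers(0, 1_000))
            else:
                cv_pos = distal.midpoint + int(rng.integers(-1_000, 1_000))
            cv = CredibleVariant(rsid=f"rsP{len(cvs):05d}", chrom=gene.chrom,
                                 pos=cv_pos, locus=locus,
                                 is_lead=not any(c.locus == locus for c in cvs))
            cvs.append(cv)
            planted_cv_positions.append((cv.chrom, cv.pos))
            for hit_gene in _genes_within_flank(index, genes, promoter):
                planted.append({"gene": hit_gene, "locus": locus,
                                "mode": mode, "cell_lines": sorted(lines)})

    # decoy loops per cell line
    loops_by_line: dict[str, list[LoopRecord]] = {c: [] for c in config.cell_lines}
    for loop, lines in planted_loops:
        for line in lines:
            loops_by_line[line].append(LoopRecord(
                loop.anchor1, loop.anchor2, loop.pet_count, loop.q_value,
                cell_line=line, loop_id=f"{line}:p{len(loops_by_line[line])}"))

    planted_points = [(c, p) for c, p in planted_cv_positions]
    for line in config.cell_lines:
        needed = config.n_loops - len(loops_by_line[line])
        k = 0
        while k < needed:
            chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            span = _draw_span(config, rng)
            if rng.random() < 0.1:  # out-of-range spans to exercise the filter
                span = int(rng.choice([3_000, 2_300_000]))
            mid1 = int(rng.integers(100_000, config.chrom_length - 100_000))
            mid2 = mid1 + span
            if mid2 + _ANCHOR_HALF > config.chrom_length:
                continue
            a1 = GenomicInterval(chrom, mid1 - _ANCHOR_HALF, mid1 + _ANCHOR_HALF)
            a2 = GenomicInterval(chrom, mid2 - _ANCHOR_HALF, mid2 + _ANCHOR_HALF)
            touches_planted_cv = any(
                c == chrom and (a1.contains(p) or a2.contains(p))
                for c, p in planted_points)
            if touches_planted_cv and (
                    _genes_within_flank(index, genes, a1)
                    or _genes_within_flank(index, genes, a2)):
                continue  # would create an unplanned target call
            q = (float(rng.uniform(0, 0.05)) if rng.random() < 0.7
                 else float(rng.uniform(0.05, 1.0)))
            loop = LoopRecord(a1, a2, pet_count=max(1, _pet_count(
                max(span, 5_000), config, rng)), q_value=q,
                cell_line=line, loop_id=f"{line}:d{k}")
            loops_by_line[line].append(loop)
            registry.add(a1)
            registry.add(a2)
            k += 1

    # decoy CVs, rejected from every anchor of every line
    for locus_i, locus in enumerate(loci):
        have = sum(1 for c in cvs if c.locus == locus)
        chrom = f"chr{locus_i % config.n_chromosomes + 1}"
        while have < config.cvs_per_locus:
            pos = int(rng.integers(50_000, config.chrom_length - 50_000))
            if registry.contains_point(chrom, pos):
                continue
            cvs.append(CredibleVariant(rsid=f"rsD{len(cvs):05d}", chrom=chrom,
                                       pos=pos, locus=locus,
                                       is_lead=have == 0))
            have += 1

    # deduplicate planted truth per (gene, locus, mode), merging cell lines
    merged: dict[tuple[str, str, str], set[str]] = {}
    for entry in planted:
        key = (entry["gene"], entry["locus"], entry["mode"])
        merged.setdefault(key, set()).update(entry["cell_lines"])
    truth = GroundTruth(
        planted_calls=[{"gene": g, "locus": l, "mode": m,
                        "cell_lines": sorted(ls)}
                       for (g, l, m), ls in sorted(merged.items())],
        true_enrichment=config.ldsc.enrichment_true,
        top_eqtls={}, eqtl_cv_genes=[])
    return loops_by_line, cvs, truth


# ---------------------------------------------------------------------------
# LDSC and eQTL inputs

def generate_ldsc_inputs(config: SimConfig, seed: int | None = None):
    """Panel + annotation + GWAS sumstats with a planted enrichment.

    The target annotation marks a random ``target_fraction`` of SNPs
    (standing in for loop-anchor membership) and carries
    ``enrichment_true`` times its SNP share of heritability.
    """
    cfg = config.ldsc
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    panel = ldsc_mod.simulate_panel(
        n_snps=cfg.n_snps, n_individuals=cfg.n_individuals,
        seed=rng)
    m = panel.n_snps
    member = np.zeros(m, dtype=bool)
    member[rng.choice(m, size=max(1, int(round(cfg.target_fraction * m))),
                      replace=False)] = True
    ann = ldsc_mod.AnnotationMatrix(
        panel.snp_ids, [ldsc_mod.BASE, "loop_anchors"],
        np.column_stack([np.ones(m, dtype=bool), member]))
    sumstats = ldsc_mod.simulate_gwas(
        panel, ann, h2=cfg.h2, enrichment_true=cfg.enrichment_true,
        n_gwas=cfg.n_gwas, seed=int(rng.integers(0, 2**31 - 1)))
    return panel, ann, sumstats


def generate_eqtl(config: SimConfig, cvs: list[CredibleVariant],
                  rng: np.random.Generator | None = None):
    """eQTL tables with known top variants; a fraction of genes get a CV
    planted as their unique top variant.  Returns (records, truth fields)."""
    from .eqtl import EqtlRecord

    rng = rng or np.random.default_rng(config.seed + 7)
    cfg = config.eqtl
    records: list[EqtlRecord] = []
    top_map: dict[str, list[str]] = {}
    cv_genes: list[str] = []
    cv_pool = [cv.rsid for cv in cvs]
    n_cv_top = round(cfg.cv_top_fraction * cfg.n_genes)
    for gi in range(cfg.n_genes):
        gene = f"EG{gi:03d}"
        p_vals = rng.uniform(1e-4, 1.0, size=cfg.variants_per_gene)
        variants = [f"rsE{gi:03d}_{vi}" for vi in range(cfg.variants_per_gene)]
        top_i = int(np.argmin(p_vals))
        p_vals[top_i] = float(rng.uniform(1e-10, 1e-6))  # unique minimum
        if gi < n_cv_top and cv_pool:
            variants[top_i] = cv_pool[int(rng.integers(len(cv_pool)))]
            cv_genes.append(gene)
        records.extend(EqtlRecord(gene, v, float(p))
                       for v, p in zip(variants, p_vals))
        top_map[gene] = [variants[top_i]]
    return records, top_map, sorted(set(cv_genes))


# ---------------------------------------------------------------------------
# bundle emission

def write_simulation(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Emit a full synthetic input bundle to ``outdir``.

    Writes genes.gtf, loops_<line>.bedpe, cvs.tsv, eqtl.tsv, truth.json and
    an ldsc/ sub-directory (panel, annotations, sumstats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = generate_genome(config, rng)
    write_genome_gtf(genes, outdir / "genes.gtf")
    loops_by_line, cvs, truth = generate_loops_and_cvs(config, genes, rng)
    for line, loops in loops_by_line.items():
        write_loops(loops, outdir / f"loops_{line}.bedpe", include_span=False)
    with (outdir / "cvs.tsv").open("w") as fh:
        fh.write("rsid\tchrom\tpos\tlocus\tis_lead\n")
        for cv in cvs:
            fh.write(f"{cv.rsid}\t{cv.chrom}\t{cv.pos}\t{cv.locus}"
                     f"\t{int(cv.is_lead)}\n")
    eqtl_records, top_map, cv_genes = generate_eqtl(config, cvs, rng)
    with (outdir / "eqtl.tsv").open("w") as fh:
        fh.write("gene\tvariant\tp_value\n")
        for rec in eqtl_records:
            fh.write(f"{rec.gene_id}\t{rec.variant}\t{rec.p_value:.6g}\n")
    ldsc_dir = outdir / "ldsc"
    ldsc_dir.mkdir(exist_ok=True)
    panel, ann, sumstats = generate_ldsc_inputs(config)
    ldsc_mod.write_panel(panel, ldsc_dir / "panel")
    ldsc_mod.write_annotations(ann, ldsc_dir / "annotations.tsv")
    ldsc_mod.write_sumstats(sumstats, ldsc_dir / "sumstats.tsv")
    truth.top_eqtls = top_map
    truth.eqtl_cv_genes = cv_genes
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    return resources.files("loop2gene.data").joinpath(name)


def load_fixture(name: str):
    """Load a packaged published-table fixture.

    ``table3`` -> list of (locus, target gene list, nearest gene list);
    ``table4`` -> 28 :class:`~loop2gene.enrich.ScoredRecord`;
    ``section2_7_counts`` -> dict of interaction-network counts;
    ``eqtl_toy`` -> (eQTL records, credible variants, target-gene set).
    """
    if name == "table3":
        rows = []
        with _data_path("table3_target_genes.tsv").open() as fh:
            fh.readline()
            for line in fh:
                locus, targets, nearest = line.rstrip("\n").split("\t")
                rows.append((locus, targets.split(","), nearest.split(",")))
        return rows
    if name == "table4":
        records = []
        with _data_path("table4_similarity_scores.tsv").open() as fh:
            fh.readline()
            for line in fh:
                gene, score, p, fdr = line.rstrip("\n").split("\t")
                records.append(ScoredRecord(id=gene, score=float(score),
                                            p_value=float(p), fdr=float(fdr)))
        return records
    if name == "section2_7_counts":
        return json.loads(_data_path("interaction_counts.json").read_text())
    if name == "eqtl_toy":
        from .eqtl import EqtlRecord

        records = []
        with _data_path("eqtl_toy.tsv").open() as fh:
            fh.readline()
            for line in fh:
                gene, variant, p = line.rstrip("\n").split("\t")
                records.append(EqtlRecord(gene, variant, float(p)))
        cv_list = []
        with _data_path("eqtl_toy_cvs.tsv").open() as fh:
            fh.readline()
            for line in fh:
                rsid, chrom, pos, locus, lead = line.rstrip("\n").split("\t")
                cv_list.append(CredibleVariant(rsid, chrom, int(pos), locus,
                                               bool(int(lead))))
        targets = {"SNX11", "HOXB2", "SRP14", "BCL11A", "HNF1B", "DMXL2"}
        return records, cv_list, targets
    raise KeyError(f"unknown fixture {name!r}; expected one of "
                   "table3, table4, section2_7_counts, eqtl_toy")
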