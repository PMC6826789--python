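"""End-to-end pipeline: filter -> annotate -> call -> integrate -> statistics.

A :class:`RunConfig` names the per-cell-line loop files, the gene models and
the credible-variant table, plus the stage thresholds (all defaulting to the
standard analysis values, so a bare run applies the canonical rules).  The
run writes one TSV per stage and a manifest recording inputs, thresholds and
package version; outputs are a pure function of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import classify_promoter_loops, locus_nearest_map, read_gene_models
from .loops import filter_loops, read_loops, summarize_loops, write_loops
from .targets import (call_target_genes, integrate_cell_lines, locus_statistics,
                      read_credible_variants)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and thresholds for a pipeline run."""

    loops: dict[str, str]         # cell line -> BEDPE path
    genes: str
    cvs: str
    out_dir: str
    min_span: int = 5_000
    max_span: int = 2_000_000
    min_pets: int = 2
    max_q: float = 0.05
    promoter_flank: int = 3_000
    fdr_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _check_inputs(config: RunConfig) -> None:
    missing = [p for p in [config.genes, config.cvs, *config.loops.values()]
               if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write one TSV per stage plus a manifest.

    Returns a result bundle with the integrated calls, per-locus summaries
    and global statistics.  Any stage error is re-raised as
    :class:`StageError` naming the stage.
    """
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []

    def _stage(name: str):
        stages_done.append(name)
        logger.info("stage: %s", name)

    try:
        _stage("read_genes")
        genes = read_gene_models(config.genes)
        _stage("read_cvs")
        cvs = read_credible_variants(config.cvs)
    except Exception as exc:
        raise StageError(f"stage {stages_done[-1]} failed: {exc}") from exc

    per_line_calls = {}
    summary_rows = []
    for line, path in sorted(config.loops.items()):
        try:
            _stage(f"filter:{line}")
            raw = read_loops(path, cell_line=line)
            kept = filter_loops(raw, min_span=config.min_span,
                                max_span=config.max_span,
                                min_pets=config.min_pets, max_q=config.max_q)
            write_loops(kept, out / f"filtered_{line}.bedpe")
            _stage(f"annotate:{line}")
            assignments = classify_promoter_loops(kept, genes,
                                                  flank=config.promoter_flank)
            promoter_idx = {a.loop_index for a in assignments}
            summary = summarize_loops(
                kept, [i in promoter_idx for i in range(len(kept))],
                cell_line=line)
            summary_rows.append(summary)
            _stage(f"call:{line}")
            per_line_calls[line] = call_target_genes(assignments, kept, cvs)
        except Exception as exc:
            raise StageError(f"stage {stages_done[-1]} failed: {exc}") from exc

    try:
        _stage("integrate")
        calls = integrate_cell_lines(per_line_calls)
        _stage("locus_statistics")
        nearest_map = locus_nearest_map(cvs, genes)
        summaries, stats = locus_statistics(calls, nearest_map)
    except Exception as exc:
        raise StageError(f"stage {stages_done[-1]} failed: {exc}") from exc

    with (out / "loop_summary.tsv").open("w") as fh:
        fh.write("cell_line\ttotal\tshort\tshort_pct\tlong\tlong_pct"
                 "\tpromoter\tpromoter_pct\tmedian_promoter_span\n")
        for s in summary_rows:
            med = "NA" if s.median_promoter_span is None else f"{s.median_promoter_span:g}"
            fh.write(f"{s.cell_line}\t{s.total}\t{s.short_loops}\t{s.short_pct}"
                     f"\t{s.long_loops}\t{s.long_pct}\t{s.promoter_loops}"
                     f"\t{s.promoter_pct}\t{med}\n")
    with (out / "target_calls.tsv").open("w") as fh:
        fh.write("locus\tgene\tmode\tcell_lines\tmulti_line\tis_nearest"
                 "\tsupporting_loops\n")
        for c in calls:
            fh.write(f"{c.locus}\t{c.gene_id}\t{c.mode}"
                     f"\t{','.join(sorted(c.cell_lines))}\t{int(c.multi_line)}"
                     f"\t{int(c.is_nearest)}\t{','.join(c.supporting_loops)}\n")
    with (out / "locus_summary.tsv").open("w") as fh:
        fh.write("locus\tn_target_genes\tnearest_overlap\tgenes\n")
        for s in summaries:
            fh.write(f"{s.locus}\t{s.n_target_genes}\t{s.nearest_overlap}"
                     f"\t{','.join(s.genes)}\n")

    manifest = {
        "version": __version__,
        "stages": stages_done,
        "inputs": {"genes": config.genes, "cvs": config.cvs,
                   "loops": dict(sorted(config.loops.items()))},
        "thresholds": {"min_span": config.min_span, "max_span": config.max_span,
                       "min_pets": config.min_pets, "max_q": config.max_q,
                       "promoter_flank": config.promoter_flank,
                       "fdr_alpha": config.fdr_alpha},
        "seed": config.seed,
        "global_stats": {
            "n_loci": stats.n_loci,
            "n_target_genes": stats.n_target_genes,
            "median_per_locus": stats.median_per_locus,
            "max_per_locus": stats.max_per_locus,
            "nearest_overlap": stats.nearest_overlap,
            "skipped_pct": stats.skipped_pct,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return {"calls": calls, "locus_summaries": summaries, "stats": stats,
            "loop_summaries": summary_rows, "manifest": manifest}
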