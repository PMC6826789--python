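"""Target-gene calling, cell-line integration and locus statistics."""

import numpy as np
import pytest

from loop2gene.annotate import GeneModel, classify_promoter_loops
from loop2gene.targets import (CredibleVariant, TargetGeneCall,
                               call_target_genes, integrate_cell_lines,
                               locus_statistics, read_credible_variants)

from conftest import make_loop


def gene(gid, tss, chrom="chr1"):
    return GeneModel(gene_id=gid, name=gid, chrom=chrom, strand="+",
                     tss_list=(tss,), biotype="coding")


def cv(rsid, pos, locus, chrom="chr1", lead=False):
    return CredibleVariant(rsid=rsid, chrom=chrom, pos=pos, locus=locus,
                           is_lead=lead)


class TestCallTargetGenes:
    def test_distal_loop_mode(self):
        # CV in anchor1; anchor2 is 1 kb from G's TSS
        loops = [make_loop(s1=100_000, e1=105_000, s2=300_000, e2=305_000)]
        genes = [gene("G", 306_000)]
        asg = classify_promoter_loops(loops, genes)
        calls = call_target_genes(asg, loops, [cv("rs1", 102_000, "L1")])
        assert [(c.gene_id, c.locus, c.mode) for c in calls] == \
               [("G", "L1", "distal_loop")]

    def test_promoter_cv_mode(self):
        # CV inside the promoter anchor itself; no CV in the distal anchor
        loops = [make_loop(s1=100_000, e1=105_000, s2=300_000, e2=305_000)]
        genes = [gene("W", 103_000)]
        asg = classify_promoter_loops(loops, genes)
        calls = call_target_genes(asg, loops, [cv("rs1", 104_000, "L1")])
        assert [(c.gene_id, c.mode) for c in calls] == [("W", "promoter_cv")]

    def test_distal_evidence_dominates_mode(self):
        loops = [make_loop(s1=100_000, e1=105_000, s2=300_000, e2=305_000)]
        genes = [gene("G", 103_000)]
        asg = classify_promoter_loops(loops, genes)
        calls = call_target_genes(asg, loops, [
            cv("rs1", 104_000, "L1"),   # promoter-side CV
            cv("rs2", 302_000, "L1"),   # distal CV
        ])
        assert [(c.gene_id, c.mode) for c in calls] == [("G", "distal_loop")]

    def test_reciprocal_promoter_promoter_loop(self):
        # promoters and CVs at both anchors: calls in both directions
        loops = [make_loop(s1=100_000, e1=105_000, s2=300_000, e2=305_000)]
        genes = [gene("A", 102_000), gene("B", 302_000)]
        asg = classify_promoter_loops(loops, genes)
        calls = call_target_genes(asg, loops, [
            cv("rs1", 101_000, "L1"), cv("rs2", 301_000, "L1")])
        assert {(c.gene_id, c.mode) for c in calls} == \
               {("A", "distal_loop"), ("B", "distal_loop")}

    def test_cv_outside_all_anchors_contributes_nothing(self):
        loops = [make_loop()]
        genes = [gene("G", 103_000)]
        asg = classify_promoter_loops(loops, genes)
        assert call_target_genes(asg, loops, [cv("rs1", 700_000, "L1")]) == []

    def test_matches_brute_force_triple_scan(self, rng):
        loops = [make_loop(s1=int(s), e1=int(s) + 5_000,
                           s2=int(s) + d, e2=int(s) + d + 5_000,
                           loop_id=f"l{i}")
                 for i, (s, d) in enumerate(zip(
                     rng.integers(0, 2_000_000, size=40),
                     rng.integers(10_000, 500_000, size=40)))]
        genes = [gene(f"G{i}", int(t))
                 for i, t in enumerate(rng.integers(0, 2_600_000, size=30))]
        cvs = [cv(f"rs{i}", int(p), f"L{i % 5}")
               for i, p in enumerate(rng.integers(0, 2_600_000, size=50))]
        asg = classify_promoter_loops(loops, genes)
        got = {(c.gene_id, c.locus, c.mode)
               for c in call_target_genes(asg, loops, cvs)}

        # oracle: scan every (assignment, CV) pair explicitly
        distal, promoter = set(), set()
        for a in asg:
            loop = loops[a.loop_index]
            same = loop.anchor1 if a.anchor_index == 1 else loop.anchor2
            other = loop.anchor2 if a.anchor_index == 1 else loop.anchor1
            for v in cvs:
                if v.chrom != loop.chrom:
                    continue
                if other.contains(v.pos):
                    distal.add((a.gene_id, v.locus))
                if same.contains(v.pos):
                    promoter.add((a.gene_id, v.locus))
        expected = {(g, l, "distal_loop") for g, l in distal} | {
            (g, l, "promoter_cv") for g, l in promoter - distal}
        assert got == expected


class TestIntegrateCellLines:
    def _call(self, g, locus, mode="distal_loop", lines=(), sup=("x",)):
        return TargetGeneCall(gene_id=g, locus=locus, mode=mode,
                              cell_lines=set(lines),
                              supporting_loops=list(sup))

    def test_multi_line_flag(self):
        merged = integrate_cell_lines({
            "a": [self._call("G", "L1", lines=["a"])],
            "b": [self._call("G", "L1", lines=["b"])],
            "c": [], "d": [],
        })
        (call,) = merged
        assert call.cell_lines == {"a", "b"}
        assert call.multi_line

    def test_disjoint_sets_union(self):
        merged = integrate_cell_lines({
            "a": [self._call("G1", "L1", lines=["a"])],
            "b": [self._call("G2", "L2", lines=["b"])],
        })
        assert len(merged) == 2
        assert not any(c.multi_line for c in merged)

    def test_distal_mode_wins_across_lines(self):
        merged = integrate_cell_lines({
            "a": [self._call("G", "L1", mode="promoter_cv", lines=["a"])],
            "b": [self._call("G", "L1", mode="distal_loop", lines=["b"])],
        })
        assert merged[0].mode == "distal_loop"

    def test_multi_line_fraction_matches_planted_evidence(self, rng):
        # build per-line calls from a known evidence map and recover the
        # fraction of genes supported by >= 2 lines
        lines = ["a", "b", "c", "d"]
        evidence = {}
        for i in range(50):
            k = 2 + int(rng.integers(0, 3)) if rng.random() < 0.4 else 1
            evidence[f"G{i}"] = set(rng.choice(lines, size=k, replace=False))
        per_line = {ln: [self._call(g, "L1", lines=[ln])
                         for g, ls in evidence.items() if ln in ls]
                    for ln in lines}
        merged = integrate_cell_lines(per_line)
        want = sum(len(ls) >= 2 for ls in evidence.values()) / len(evidence)
        got = sum(c.multi_line for c in merged) / len(merged)
        assert got == pytest.approx(want)


class TestLocusStatistics:
    def test_single_locus_single_nearest_gene(self):
        calls = [TargetGeneCall("G", "L1", "distal_loop", {"a"}, ["x"])]
        summaries, stats = locus_statistics(calls, {"L1": {"G"}})
        assert stats.n_loci == 1
        assert stats.median_per_locus == 1
        assert stats.nearest_overlap == 1
        assert stats.skipped_pct == 0.0
        assert calls[0].is_nearest

    def test_permutation_invariance(self, rng):
        calls = [TargetGeneCall(f"G{i}", f"L{i % 3}", "distal_loop",
                                {"a"}, ["x"]) for i in range(12)]
        nearest = {"L0": {"G0"}, "L1": {"G4"}, "L2": set()}
        _, ref = locus_statistics(list(calls), nearest)
        perm = list(calls)
        rng.shuffle(perm)
        _, got = locus_statistics(perm, nearest)
        assert (got.n_loci, got.median_per_locus, got.nearest_overlap,
                got.per_locus_counts) == \
               (ref.n_loci, ref.median_per_locus, ref.nearest_overlap,
                ref.per_locus_counts)

    def test_nearest_overlap_bounded_by_totals(self):
        calls = [TargetGeneCall(f"G{i}", "L1", "distal_loop", {"a"}, ["x"])
                 for i in range(5)]
        summaries, stats = locus_statistics(
            calls, {"L1": {"G0", "G1", "NOT_CALLED"}})
        assert stats.nearest_overlap <= stats.n_target_genes
        assert summaries[0].nearest_overlap <= summaries[0].n_target_genes

    def test_empty_calls(self):
        summaries, stats = locus_statistics([], {})
        assert summaries == [] and stats.n_loci == 0
        assert stats.median_per_locus is None


def test_read_credible_variants(tmp_path):
    path = tmp_path / "cvs.tsv"
    path.write_text("rsid\tchrom\tpos\tlocus\tis_lead\n"
                    "rs1\tchr1\t100\tL1\t1\n"
                    "rs2\tchr2\t500\tL2\t0\n")
    cvs = read_credible_variants(path)
    assert [(c.rsid, c.chrom, c.pos, c.locus, c.is_lead) for c in cvs] == [
        ("rs1", "chr1", 100, "L1", True), ("rs2", "chr2", 500, "L2", False)]
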