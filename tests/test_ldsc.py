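"""Partitioned LD scores, the heritability regression, and the GWAS simulator."""

import numpy as np
import pytest

from loop2gene import ldsc
from loop2gene.ldsc import (AnnotationMatrix, SumStats, VariantPanel,
                            apply_region_filter, compute_ld_scores,
                            fit_partitioned_regression, simulate_gwas,
                            simulate_panel)


def tiny_panel(genotypes, positions=None, chroms=None):
    geno = np.asarray(genotypes, dtype=np.int8)
    m = geno.shape[1]
    positions = np.arange(m) * 1_000 if positions is None else positions
    chroms = np.full(m, "chr1") if chroms is None else chroms
    return VariantPanel(np.array([f"s{i}" for i in range(m)]),
                        np.asarray(chroms), np.asarray(positions), geno)


def base_only(panel):
    return AnnotationMatrix(panel.snp_ids, ["base"],
                            np.ones((panel.n_snps, 1), dtype=bool))


def brute_force_scores(panel, annotations, window):
    """O(M^2) oracle: full pairwise adjusted r^2 within the window."""
    g = panel.genotypes.astype(float)
    g = (g - g.mean(0)) / g.std(0)
    n = panel.n_ref
    r2 = (g.T @ g / n) ** 2
    r2_adj = r2 - (1 - r2) / (n - 2)
    m = panel.n_snps
    out = np.zeros((m, len(annotations.names)))
    for j in range(m):
        for k in range(m):
            if panel.chroms[j] != panel.chroms[k]:
                continue
            if abs(int(panel.positions[j]) - int(panel.positions[k])) > window:
                continue
            out[j] += r2_adj[j, k] * annotations.matrix[k]
    return out


class TestLdScores:
    def test_single_snp_base_score_is_one(self):
        panel = tiny_panel([[0], [1], [2], [1], [0]])
        scores = compute_ld_scores(panel, base_only(panel))
        assert scores.base == pytest.approx([1.0])

    def test_three_snp_hand_panel_matches_direct_computation(self):
        geno = [[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 1, 2], [2, 1, 0]]
        panel = tiny_panel(geno)
        ann = base_only(panel)
        scores = compute_ld_scores(panel, ann, window=10_000)
        assert scores.scores == pytest.approx(
            brute_force_scores(panel, ann, 10_000))

    def test_snp_outside_window_of_category_scores_zero(self):
        # target category holds only the far-away SNP
        geno = np.array([[0, 1], [1, 2], [2, 0], [1, 1], [0, 2]])
        panel = tiny_panel(geno, positions=np.array([0, 5_000_000]))
        ann = AnnotationMatrix(panel.snp_ids, ["base", "far"],
                               np.array([[True, False], [True, True]]))
        scores = compute_ld_scores(panel, ann, window=1_000_000)
        assert scores.scores[0, 1] == 0.0          # not a member, out of window
        assert scores.scores[1, 1] == pytest.approx(1.0)  # its own self-term

    def test_matches_brute_force_on_random_panel(self):
        panel = simulate_panel(n_snps=300, n_individuals=60,
                               pool_haplotypes=200, ld_segment_snps=60,
                               seed=9)
        rng = np.random.default_rng(1)
        member = rng.random(panel.n_snps) < 0.2
        ann = AnnotationMatrix(
            panel.snp_ids, ["base", "target"],
            np.column_stack([np.ones(panel.n_snps, bool), member]))
        window = 60_000
        scores = compute_ld_scores(panel, ann, window=window)
        assert scores.scores == pytest.approx(
            brute_force_scores(panel, ann, window), abs=1e-9)
        # a sub-category never exceeds the base score
        assert np.all(scores.scores[:, 1] <= scores.base + 1e-12)

    def test_small_reference_rejected(self):
        panel = tiny_panel([[0], [2]])
        with pytest.raises(ValueError, match="n_ref"):
            compute_ld_scores(panel, base_only(panel))


class TestAnnotationMatrix:
    def test_base_category_required(self):
        with pytest.raises(ValueError, match="base"):
            AnnotationMatrix(np.array(["s0"]), ["other"],
                             np.ones((1, 1), dtype=bool))

    def test_base_must_cover_all_snps(self):
        with pytest.raises(ValueError, match="every SNP"):
            AnnotationMatrix(np.array(["s0", "s1"]), ["base"],
                             np.array([[True], [False]]))


@pytest.fixture(scope="module")
def small_inputs():
    panel = simulate_panel(n_snps=2_000, n_individuals=200,
                           pool_haplotypes=800, seed=3)
    rng = np.random.default_rng(3)
    member = np.zeros(panel.n_snps, dtype=bool)
    member[rng.choice(panel.n_snps, size=panel.n_snps // 10,
                      replace=False)] = True
    ann = AnnotationMatrix(
        panel.snp_ids, ["base", "target"],
        np.column_stack([np.ones(panel.n_snps, bool), member]))
    return panel, ann


class TestRegression:
    def test_base_only_enrichment_is_exactly_one(self, small_inputs):
        panel, _ = small_inputs
        ann = base_only(panel)
        ss = simulate_gwas(panel, ann, h2=0.4, enrichment_true=1.0,
                           n_gwas=1_000, seed=5)
        scores = compute_ld_scores(panel, ann)
        fit = fit_partitioned_regression(ss, scores, ann)
        assert fit.enrichment[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.se[0] == pytest.approx(0.0, abs=1e-9)

    def test_base_enrichment_is_one_with_target_category(self, small_inputs):
        panel, ann = small_inputs
        ss = simulate_gwas(panel, ann, h2=0.4, enrichment_true=3.0,
                           n_gwas=1_000, seed=6)
        scores = compute_ld_scores(panel, ann)
        fit = fit_partitioned_regression(ss, scores, ann)
        assert fit.enrichment[ann.names.index("base")] == pytest.approx(1.0)
        assert fit.h2_total == pytest.approx(
            fit.h2_cat[ann.names.index("base")])

    def test_collinear_categories_rejected(self, small_inputs):
        panel, ann = small_inputs
        dup = AnnotationMatrix(
            panel.snp_ids, ["base", "target", "target_copy"],
            np.column_stack([ann.matrix, ann.matrix[:, 1]]))
        ss = simulate_gwas(panel, ann, h2=0.4, enrichment_true=1.0,
                           n_gwas=1_000, seed=7)
        scores = compute_ld_scores(panel, dup)
        with pytest.raises(ValueError, match="target"):
            fit_partitioned_regression(ss, scores, dup)

    def test_null_jackknife_interval_covers_one(self, small_inputs):
        panel, ann = small_inputs
        scores = compute_ld_scores(panel, ann)
        covered = 0
        n_rep = 25
        for rep in range(n_rep):
            ss = simulate_gwas(panel, ann, h2=0.4, enrichment_true=1.0,
                               n_gwas=1_000, seed=100 + rep)
            fit = fit_partitioned_regression(ss, scores, ann)
            i = ann.names.index("target")
            lo = fit.enrichment[i] - 1.96 * fit.se[i]
            hi = fit.enrichment[i] + 1.96 * fit.se[i]
            covered += lo <= 1.0 <= hi
        # approximate 95% interval: allow for jackknife/finite-block error
        assert covered / n_rep >= 0.8

    def test_summary_mentions_categories(self, small_inputs):
        panel, ann = small_inputs
        ss = simulate_gwas(panel, ann, h2=0.4, enrichment_true=2.0,
                           n_gwas=1_000, seed=8)
        scores = compute_ld_scores(panel, ann)
        text = fit_partitioned_regression(ss, scores, ann).summary()
        assert "base" in text and "target" in text and "enrichment" in text


@pytest.fixture(scope="module")
def panel_ann():
    panel = simulate_panel(n_snps=1_500, n_individuals=150,
                           pool_haplotypes=600, seed=4)
    rng = np.random.default_rng(4)
    member = rng.random(panel.n_snps) < 0.2
    ann = AnnotationMatrix(
        panel.snp_ids, ["base", "target"],
        np.column_stack([np.ones(panel.n_snps, bool), member]))
    return panel, ann


class TestSimulateGwas:
    def test_null_gwas_mean_chi2_near_one(self, panel_ann):
        panel, ann = panel_ann
        ss = simulate_gwas(panel, ann, h2=0.0, enrichment_true=1.0,
                           n_gwas=2_000, seed=11)
        assert ss.chi2.mean() == pytest.approx(1.0, abs=0.1)

    def test_flat_enrichment_balances_categories(self, panel_ann):
        panel, ann = panel_ann
        chi2 = np.zeros(panel.n_snps)
        for rep in range(4):
            ss = simulate_gwas(panel, ann, h2=0.5, enrichment_true=1.0,
                               n_gwas=2_000, seed=30 + rep)
            chi2 += ss.chi2 / 4
        member = ann.matrix[:, 1]
        assert chi2[member].mean() == pytest.approx(chi2[~member].mean(),
                                                    rel=0.15)

    def test_deterministic_under_seed(self, panel_ann):
        panel, ann = panel_ann
        a = simulate_gwas(panel, ann, h2=0.3, enrichment_true=2.0,
                          n_gwas=500, seed=77)
        b = simulate_gwas(panel, ann, h2=0.3, enrichment_true=2.0,
                          n_gwas=500, seed=77)
        assert np.array_equal(a.chi2, b.chi2)

    def test_infeasible_variance_split_rejected(self, panel_ann):
        panel, ann = panel_ann
        with pytest.raises(ValueError, match="infeasible"):
            simulate_gwas(panel, ann, h2=0.5, enrichment_true=50.0,
                          n_gwas=500, seed=1)

    def test_panel_without_pool_rejected(self, panel_ann):
        panel, ann = panel_ann
        bare = VariantPanel(panel.snp_ids, panel.chroms, panel.positions,
                            panel.genotypes)
        with pytest.raises(ValueError, match="pool"):
            simulate_gwas(bare, ann, h2=0.3, enrichment_true=1.0,
                          n_gwas=500, seed=1)


class TestRegionFilterAndIo:
    def test_region_filter_drops_snps_consistently(self):
        panel = simulate_panel(n_snps=200, n_individuals=30,
                               pool_haplotypes=100, seed=2)
        ann = base_only(panel)
        ss = SumStats(panel.snp_ids, np.ones(panel.n_snps), 1_000)
        lo, hi = int(panel.positions[50]), int(panel.positions[100])
        p2, a2, s2 = apply_region_filter(panel, ann, ss,
                                         exclude=[("chr1", lo, hi)])
        assert p2.n_snps < panel.n_snps
        assert not np.any((p2.positions >= lo) & (p2.positions < hi))
        assert a2.n_snps == p2.n_snps
        assert np.array_equal(s2.snp_ids, p2.snp_ids)

    def test_io_round_trips(self, tmp_path):
        panel = simulate_panel(n_snps=50, n_individuals=20,
                               pool_haplotypes=60, seed=6)
        ann = AnnotationMatrix(
            panel.snp_ids, ["base", "t"],
            np.column_stack([np.ones(50, bool),
                             np.arange(50) % 3 == 0]))
        ss = SumStats(panel.snp_ids, np.linspace(0.1, 4.0, 50), 9_999)
        ldsc.write_panel(panel, tmp_path / "p")
        ldsc.write_annotations(ann, tmp_path / "a.tsv")
        ldsc.write_sumstats(ss, tmp_path / "s.tsv")
        p2 = ldsc.read_panel(tmp_path / "p")
        a2 = ldsc.read_annotations(tmp_path / "a.tsv")
        s2 = ldsc.read_sumstats(tmp_path / "s.tsv")
        assert np.array_equal(p2.genotypes, panel.genotypes)
        assert np.array_equal(p2.positions, panel.positions)
        assert np.array_equal(a2.matrix, ann.matrix)
        assert s2.n == 9_999
        assert s2.chi2 == pytest.approx(ss.chi2, rel=1e-5)
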