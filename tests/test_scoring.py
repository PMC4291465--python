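"""Fold-changes, tag weighting, lifespan/growth scores, calls, comparisons."""

import copy
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from barseqcls import CountMatrix, SampleMeta, SimConfig, sample_counts, simulate_trajectories
from barseqcls.scoring import (
    INTERMEDIATE,
    LONG_LIVED,
    NOT_SCORED,
    SHORT_FLAG,
    BarSeqScreen,
    ScoringConfig,
    compare_screens,
    correlate_scores,
    enrichment,
    weighted_combine,
)
from conftest import cls_samples, make_count_matrix


class TestWeightedCombine:
    def test_symmetric_tags_average_evenly(self):
        w = weighted_combine(10, 10, 10, 10, fc_up=2.0, fc_dn=4.0)
        assert w.w_up == 0.5 and w.fc_combined == pytest.approx(3.0)

    def test_printed_formula_hand_evaluation(self):
        # direct evaluation: w_up = (30+10)/(30+10+10+10) = 2/3
        w = weighted_combine(30, 10, 10, 10, fc_up=3.0, fc_dn=1.0)
        assert w.w_up == pytest.approx(2 / 3)
        assert w.fc_combined == pytest.approx(7 / 3)

    def test_single_tag_gets_full_weight(self):
        w = weighted_combine(30, 0, 10, 0, fc_up=3.0, fc_dn=None)
        assert w.w_up == 1.0 and w.fc_combined == 3.0

    def test_both_invalid_is_invalid(self):
        assert not weighted_combine(0, 0, 0, 0, None, None).valid

    def test_convex_combination_bounds(self, rng):
        for _ in range(200):
            up_i, dn_i, up_0, dn_0 = rng.integers(1, 1000, size=4)
            fc_up, fc_dn = rng.uniform(0, 5, size=2)
            w = weighted_combine(up_i, dn_i, up_0, dn_0, fc_up, fc_dn)
            assert 0 <= w.w_up <= 1
            assert w.w_up + w.w_dn == pytest.approx(1.0)
            assert min(fc_up, fc_dn) - 1e-12 <= w.fc_combined <= max(fc_up, fc_dn) + 1e-12


def two_rep_matrix(rep1_counts, rep2_counts, depth=10_000, timepoints=(0.0, 4.0, 8.0, 12.0)):
    """One up-only gene with given counts per timepoint, plus a filler gene
    absorbing the rest so every sample has identical depth."""
    samples = cls_samples(2, timepoints)
    cells = {("gene", "up"): {}, ("filler", "up"): {}}
    for rep, counts in ((1, rep1_counts), (2, rep2_counts)):
        for t, c in zip(timepoints, counts):
            sid = f"rep{rep}_t{t:g}"
            cells[("gene", "up")][sid] = c
            cells[("filler", "up")][sid] = depth - c
    return make_count_matrix(cells, samples)


class TestFoldChanges:
    def test_depth_normalized_ratio(self):
        cm = two_rep_matrix([50, 100, 100, 100], [50, 100, 100, 100])
        fc = BarSeqScreen(cm).fold_changes()
        row = fc[(fc.gene_id == "gene") & (fc.replicate == 1) & (fc.timepoint == 4.0)]
        assert row.fc.iloc[0] == pytest.approx(2.0)  # (100/1e4)/(50/1e4)

    def test_reference_against_itself_is_unity(self):
        cm = two_rep_matrix([100] * 4, [100] * 4)
        screen = BarSeqScreen(cm)
        fc = screen.fold_changes()
        present = fc[(fc.gene_id == "gene") & (fc.tag_kind == "up")]
        assert np.allclose(present.fc, 1.0)

    def test_below_min_reads_is_invalid(self):
        cm = two_rep_matrix([100, 9, 100, 100], [100] * 4)
        fc = BarSeqScreen(cm).fold_changes()
        row = fc[(fc.gene_id == "gene") & (fc.replicate == 1) & (fc.timepoint == 4.0)]
        assert not row.valid.iloc[0]

    def test_missing_reference_sample_is_error(self):
        samples = [SampleMeta("a", 1, 4.0, "weeks", "aged")]
        cm = make_count_matrix({("g", "up"): {"a": 100}}, samples)
        with pytest.raises(ValueError, match="reference"):
            BarSeqScreen(cm)


class TestLifespanScore:
    def test_constant_pool_proportion_scores_one(self):
        cm = two_rep_matrix([100] * 4, [100] * 4)
        res = BarSeqScreen(cm).fit()
        assert res.table.loc["gene", "score"] == pytest.approx(1.0)
        assert res.table.loc["gene", "call"] == INTERMEDIATE

    def test_replicate_medians_average_to_score(self):
        # oracle: brute-force median/mean over the enumerated fold-changes
        rep1 = [100, 160, 180, 200]  # fcs 1.6, 1.8, 2.0 -> median 1.8
        rep2 = [100, 110, 120, 130]  # fcs 1.1, 1.2, 1.3 -> median 1.2
        expect = statistics.mean(
            [
                statistics.median([c / 100 for c in rep[1:]])
                for rep in (rep1, rep2)
            ]
        )
        cm = two_rep_matrix(rep1, rep2)
        res = BarSeqScreen(cm).fit()
        assert res.table.loc["gene", "score"] == pytest.approx(expect) == 1.5
        assert res.table.loc["gene", "call"] == LONG_LIVED  # 1.5 > 1.44

    def test_all_timepoints_below_threshold_not_scored(self):
        cm = two_rep_matrix([100, 5, 5, 5], [100, 5, 5, 5])
        res = BarSeqScreen(cm).fit()
        assert res.table.loc["gene", "call"] == NOT_SCORED
        assert math.isnan(res.table.loc["gene", "score"])

    def test_single_replicate_gene_flagged(self):
        cm = two_rep_matrix([100, 150, 150, 150], [100, 5, 5, 5])
        res = BarSeqScreen(cm).fit()
        assert res.table.loc["gene", "score"] == pytest.approx(1.5)
        assert bool(res.table.loc["gene", "single_replicate"])

    def test_growth_mode_identity(self):
        # same machinery with the 120-min reference sample
        samples = cls_samples(2, (120.0, 230.0, 340.0, 460.0, 550.0))
        cells = {("gene", "up"): {}, ("filler", "up"): {}}
        for m in samples:
            cells[("gene", "up")][m.sample_id] = 200
            cells[("filler", "up")][m.sample_id] = 9800
        res = BarSeqScreen(make_count_matrix(cells, samples)).fit()
        assert res.table.loc["gene", "score"] == pytest.approx(1.0)

    def test_weighting_pulls_combined_fc_toward_covered_tag(self):
        samples = cls_samples(1, (0.0, 4.0))
        cells = {
            ("gene", "up"): {"rep1_t0": 10, "rep1_t4": 30},
            ("gene", "dn"): {"rep1_t0": 10, "rep1_t4": 10},
            ("filler", "up"): {"rep1_t0": 9980, "rep1_t4": 9960},
        }
        res = BarSeqScreen(make_count_matrix(cells, samples)).fit()
        # fc_up = 3, fc_dn = 1, w_up = 40/60 -> 7/3 (hand oracle)
        assert res.table.loc["gene", "score"] == pytest.approx(7 / 3)


class TestScoreInvariances:
    def make_sim_matrix(self, seed=42):
        # constant-composition pool so the <10-read filter cannot bind
        cfg = SimConfig(n_genes=120, depth=300_000, abundance_sigma=0.2,
                        long_lived_fraction=1.0, seed=seed)
        return sample_counts(simulate_trajectories(cfg))

    def test_invariant_to_gene_and_sample_order(self):
        cm = self.make_sim_matrix()
        res1 = BarSeqScreen(cm).fit()
        rng = np.random.default_rng(0)
        shuffled = cm.counts.iloc[rng.permutation(len(cm.counts))]
        shuffled = shuffled[list(np.array(cm.sample_ids)[rng.permutation(len(cm.sample_ids))])]
        cm2 = CountMatrix(counts=shuffled, samples=list(reversed(cm.samples)))
        res2 = BarSeqScreen(cm2).fit()
        pd.testing.assert_series_equal(res1.table["score"], res2.table["score"])

    def test_single_sample_rescale_normalized_weights(self):
        cm = self.make_sim_matrix()
        assert cm.counts.values.min() >= 10  # filter must not bind
        cfg = ScoringConfig(normalized_weights=True)
        base = BarSeqScreen(cm, cfg).fit()
        scaled = copy.deepcopy(cm.counts)
        scaled[cm.sample_ids[2]] *= 13
        res = BarSeqScreen(CountMatrix(scaled, cm.samples), cfg).fit()
        assert np.allclose(base.table["score"], res.table["score"])

    def test_common_rescale_raw_weights(self):
        cm = self.make_sim_matrix()
        base = BarSeqScreen(cm).fit()
        res = BarSeqScreen(CountMatrix(cm.counts * 3, cm.samples)).fit()
        assert np.allclose(base.table["score"], res.table["score"])


class TestCalls:
    def test_strict_threshold_semantics(self):
        samples = cls_samples(1, (0.0, 4.0))
        depth = 100_000
        cells = {}
        for gene, fc in (("A", 1.45), ("B", 1.44), ("C", 0.13)):
            cells[(gene, "up")] = {"rep1_t0": 2000, "rep1_t4": int(2000 * fc)}
        used = {sid: sum(c[sid] for c in cells.values()) for sid in ("rep1_t0", "rep1_t4")}
        cells[("filler", "up")] = {sid: depth - used[sid] for sid in used}
        res = BarSeqScreen(make_count_matrix(cells, samples)).fit()
        assert res.long_lived == ["A"]
        assert res.short_flagged == ["C"]
        assert res.table.loc["B", "call"] == INTERMEDIATE

    def test_long_lived_ordered_by_descending_score(self):
        samples = cls_samples(1, (0.0, 4.0))
        cells = {
            ("x", "up"): {"rep1_t0": 1000, "rep1_t4": 2000},
            ("y", "up"): {"rep1_t0": 1000, "rep1_t4": 3000},
            ("filler", "up"): {"rep1_t0": 8000, "rep1_t4": 5000},
        }
        res = BarSeqScreen(make_count_matrix(cells, samples)).fit()
        assert res.long_lived == ["y", "x"]


class TestCompareScreens:
    def test_partial_overlap(self):
        out = compare_screens({"x", "y"}, {"y", "z"})
        assert out["overlap"] == 1 and out["unique_to_b"] == ["z"]
        assert out["jaccard"] == pytest.approx(1 / 3)

    def test_identical_sets(self):
        out = compare_screens({"a", "b"}, {"a", "b"})
        assert out["overlap"] == 2 and out["jaccard"] == 1.0

    def test_disjoint_sets(self):
        assert compare_screens({"a"}, {"b"})["overlap"] == 0


class TestCorrelateScores:
    def test_identical_vectors_correlate_perfectly(self):
        s = pd.Series([0.5, 1.0, 1.5, 2.0], index=list("abcd"))
        n, r, _ = correlate_scores(s, s)
        assert n == 4 and r == pytest.approx(1.0)

    def test_antisymmetric_vectors_anticorrelate(self):
        x = pd.Series([0.5, 1.0, 1.5, 2.0], index=list("abcd"))
        y = pd.Series((2 * x.mean() - x).values, index=x.index)
        _, r, _ = correlate_scores(x, y)
        assert r == pytest.approx(-1.0)

    def test_score_floor_restricts_n(self):
        x = pd.Series([0.1, 0.5, 1.0, 1.5, 2.0], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 1.2, 0.7, 1.9], index=list("abcde"))
        n, _, _ = correlate_scores(x, y, min_lifespan=0.4)
        assert n == 4

    def test_too_few_genes_is_error(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            correlate_scores(s, s)


class TestEnrichment:
    def test_saturated_overlap_is_uninformative(self):
        genes = {f"g{i}" for i in range(10)}
        p, fold = enrichment(genes, genes, genes)
        assert p == pytest.approx(1.0) and fold == pytest.approx(1.0)

    def test_perfect_overlap_exact_probability(self):
        # oracle: P(all 10 hits in the 10-gene category) = 1/C(100,10)
        universe = {f"g{i}" for i in range(100)}
        category = {f"g{i}" for i in range(10)}
        p, fold = enrichment(category, category, universe)
        assert p == pytest.approx(1 / comb(100, 10, exact=True))
        assert fold == pytest.approx(10.0)

    def test_zero_overlap(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(5)}
        category = {f"g{i}" for i in range(50, 90)}
        p, fold = enrichment(hits, category, universe)
        assert fold == 0.0 and p > 0.9

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            enrichment(set(), set(), set())
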