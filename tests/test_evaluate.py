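"""Metrics, paired t-tests, per-gene ANOVA, min-max normalisation, CV plan."""

import numpy as np
import pytest
from scipy import stats

from omicstack.annotate import OmicsMatrix, build_gene_table
from omicstack.evaluate import (CVPlan, anova_per_gene, anova_table,
                                compute_metrics, minmax_normalize,
                                paired_ttest)


class TestComputeMetrics:
    classes = np.array(["a", "b", "c"])

    def test_perfect_predictions_give_ones(self):
        y = np.array(list("abc") * 4)
        probs = np.zeros((12, 3))
        probs[np.arange(12), [self.classes.tolist().index(c) for c in y]] = 1.0
        m = compute_metrics(y, probs, self.classes)
        assert all(np.isclose(m[k], 1.0) for k in m)

    def test_uniform_probabilities_are_no_skill(self):
        y = np.array(list("abc") * 10)
        probs = np.full((30, 3), 1 / 3)
        m = compute_metrics(y, probs, self.classes)
        assert abs(m["roc_auc"] - 0.5) < 1e-9
        assert abs(m["accuracy"] - 1 / 3) < 1e-9

    def test_six_sample_toy_matches_hand_computation(self):
        # y:      a    a    b    b    c    c
        # pred:   a    b    b    b    c    a   (from the rows below)
        y = np.array(list("aabbcc"))
        probs = np.array([
            [0.7, 0.2, 0.1],
            [0.2, 0.6, 0.2],
            [0.1, 0.8, 0.1],
            [0.3, 0.5, 0.2],
            [0.1, 0.2, 0.7],
            [0.5, 0.3, 0.2],
        ])
        m = compute_metrics(y, probs, self.classes)
        # per class: a: TP1 FP1 FN1 -> P=R=F1=0.5; b: TP2 FP1 FN0 -> P=2/3,R=1,
        # F1=0.8; c: TP1 FP0 FN1 -> P=1, R=0.5, F1=2/3
        assert abs(m["accuracy"] - 4 / 6) < 1e-9
        assert abs(m["f1"] - np.mean([0.5, 0.8, 2 / 3])) < 1e-9
        assert abs(m["precision"] - np.mean([0.5, 2 / 3, 1.0])) < 1e-9
        assert abs(m["recall"] - np.mean([0.5, 1.0, 0.5])) < 1e-9

    def test_absent_class_excluded_from_auc(self):
        y = np.array(list("abab"))
        probs = np.array([[0.6, 0.3, 0.1]] * 4)
        m = compute_metrics(y, probs, self.classes)
        assert np.isfinite(m["roc_auc"])

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array(["a"]), np.array([[0.9, 0.3, 0.1]]),
                            self.classes)


class TestPairedTTest:
    def test_matches_closed_form_on_printed_toy(self):
        d = np.array([0.01, -0.02, 0.03, 0.00, 0.02])
        a = np.full(5, 0.8) + d
        b = np.full(5, 0.8)
        t, p = paired_ttest(a, b)
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=4)
        assert abs(t - t_ref) < 1e-12 and abs(p - p_ref) < 1e-12

    def test_identical_vectors(self):
        v = np.array([0.9, 0.8, 0.85])
        assert paired_ttest(v, v) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerates(self):
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.9])
        t, p = paired_ttest(a, a - 0.2)
        assert t == np.inf and p == 0.0
        t, p = paired_ttest(a - 0.2, a)
        assert t == -np.inf and p == 0.0

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            paired_ttest(np.array([1.0]), np.array([0.5]))


class TestAnova:
    labels = np.repeat(np.array(["x", "y", "z"]), 30)

    def test_strong_shift_is_significant(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(90)
        v[self.labels == "z"] += 3.0
        res = anova_per_gene("G", {"mrna": v}, self.labels)
        assert res.lowest_p < 1e-10
        assert res.best_omic == "RNASeq"

    def test_identical_groups_give_null_f(self):
        v = np.tile(np.arange(30, dtype=float), 3)  # same values per group
        res = anova_per_gene("G", {"mrna": v}, self.labels)
        assert res.f_stats["RNASeq"] < 1e-12
        assert res.p_values["RNASeq"] > 0.999

    def test_all_zero_channel_skipped(self):
        rng = np.random.default_rng(1)
        meth = rng.standard_normal(90)
        meth[self.labels == "x"] += 2
        res = anova_per_gene(
            "G", {"mrna": rng.standard_normal(90), "meth": meth,
                  "mirna": np.zeros(90)}, self.labels)
        assert res.best_omic in ("RNASeq", "Methylation")
        assert "miRNA" not in res.p_values

    def test_single_group_skipped_with_flag(self):
        res = anova_per_gene("G", {"mrna": np.ones(5)},
                             np.array(["x"] * 5))
        assert res.skipped

    def test_table_covers_all_genes(self):
        samples = [f"s{i}" for i in range(90)]
        mrna = OmicsMatrix(np.random.default_rng(2).standard_normal((90, 3)),
                           samples, ["GA", "GB", "GC"], "mrna")
        gt = build_gene_table(mrna, None, None)
        table = anova_table(gt, self.labels)
        assert list(table["gene"]) == gt.genes
        assert table["p_value"].between(0, 1).all()


class TestMinMax:
    def test_simple_example(self):
        assert np.allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_constant_maps_to_half(self):
        assert np.allclose(minmax_normalize([5, 5, 5]), 0.5)

    def test_bounds_for_nonconstant_input(self):
        v = minmax_normalize(np.random.default_rng(0).standard_normal(50))
        assert v.min() == 0.0 and v.max() == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([]))


class TestCVPlan:
    def test_partition_and_stratification(self):
        y = np.repeat(np.array(["a", "b", "c"]), (60, 60, 20))
        plan = CVPlan(n_folds=5, n_repeats=3, seed=0)
        folds = list(plan.folds(y))
        assert len(folds) == 15
        for repeat in range(3):
            test_union = np.concatenate(
                [te for r, f, tr, te in folds if r == repeat])
            assert sorted(test_union) == list(range(140))
        for _, _, tr, te in folds:
            assert set(tr) | set(te) == set(range(140))
            assert not set(tr) & set(te)
            # per-fold class proportions within one sample of global
            _, c = np.unique(y[te], return_counts=True)
            assert np.all(np.abs(c - np.array([12, 12, 4])) <= 1)
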