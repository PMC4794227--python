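"""Dataset protocol (balance, over-sampling, splits) and evaluation metrics."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from entprise import (
    ConfusionCounts,
    VariantRecord,
    allele_frequency_filter,
    balance_status,
    confusion,
    false_positive_rate,
    fpr_cross_regression,
    grouped_kfold,
    metrics,
    oversample_balanced,
    roc_auc,
    split_variants,
)


def _variants(pid, n_disease, n_neutral, start=1):
    out = []
    pos = start
    for label, n in ((1, n_disease), (0, n_neutral)):
        for _ in range(n):
            out.append(VariantRecord(pid, pos, "A", "V", label=label))
            pos += 1
    return out


class TestBalanceStatus:
    @pytest.mark.parametrize(
        "nd, nn, balanced",
        [
            (3, 3, True),    # ratio 1.0
            (1, 4, False),   # ratio 4.0
            (0, 5, False),   # no disease variants -> ratio inf
            (10, 3, True),   # ratio 0.3, inclusive lower bound
            (1, 3, True),    # ratio 3.0, inclusive upper bound
            (10, 2, False),  # ratio 0.2
        ],
    )
    def test_ratio_window(self, nd, nn, balanced):
        status = balance_status(_variants("P", nd, nn))["P"]
        assert status.balanced is balanced
        if nd == 0:
            assert math.isinf(status.ratio)

    def test_unlabeled_variant_rejected(self):
        with pytest.raises(ValueError):
            balance_status([VariantRecord("P", 1, "A", "V")])


class TestOversampling:
    def test_count_identity_per_class(self):
        train = _variants("bal", 4, 5) + _variants("unbal", 1, 20)
        out = oversample_balanced(train, copies=6)
        n_disease = sum(v.label for v in out)
        n_neutral = len(out) - n_disease
        assert n_disease == 6 * 4 + 1
        assert n_neutral == 6 * 5 + 20

    def test_no_balanced_proteins_is_identity(self):
        train = _variants("unbal", 1, 20)
        assert oversample_balanced(train) == train

    def test_bad_copy_count_rejected(self):
        with pytest.raises(ValueError):
            oversample_balanced(_variants("P", 1, 1), copies=0)


class TestSplit:
    def test_even_split_reproducible(self):
        variants = _variants("P", 5, 5)
        a = split_variants(variants, 0.5, seed=7)
        b = split_variants(variants, 0.5, seed=7)
        assert a == b
        assert len(a[0]) == len(a[1]) == 5

    def test_odd_split_sizes_differ_by_at_most_one(self):
        tr, te = split_variants(_variants("P", 6, 5), 0.5, seed=3)
        assert abs(len(tr) - len(te)) <= 1

    def test_partition_property(self):
        variants = _variants("P", 7, 6)
        tr, te = split_variants(variants, 0.5, seed=11)
        assert sorted(map(repr, tr + te)) == sorted(map(repr, variants))
        assert not set(map(id, tr)) & set(map(id, te))


class TestGroupedKfold:
    def test_groups_never_split_across_folds(self):
        variants = []
        for g in range(4):
            variants += _variants(f"P{g}", 2, 2)
        group_of = lambda pid: pid  # noqa: E731
        folds = grouped_kfold(variants, group_of, k=2, seed=0)
        for train, test in folds:
            assert not {v.protein_id for v in train} & {v.protein_id for v in test}

    def test_isoforms_in_one_group_stay_together(self):
        variants = _variants("P1-iso1", 2, 2) + _variants("P1-iso2", 1, 1) + \
            _variants("P2", 2, 2) + _variants("P3", 2, 2)
        group_of = lambda pid: pid.split("-")[0]  # noqa: E731
        for train, test in grouped_kfold(variants, group_of, k=3, seed=1):
            test_groups = {group_of(v.protein_id) for v in test}
            train_groups = {group_of(v.protein_id) for v in train}
            assert not test_groups & train_groups

    def test_equal_groups_give_balanced_folds(self):
        variants = []
        for g in range(20):
            variants += _variants(f"P{g}", 2, 2)
        folds = grouped_kfold(variants, lambda pid: pid, k=10, seed=5)
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 4  # within +/- 1 group of 4 variants
        assert sum(sizes) == len(variants)

    def test_union_of_test_folds_is_everything(self):
        variants = _variants("P1", 3, 3) + _variants("P2", 2, 2) + _variants("P3", 1, 1)
        folds = grouped_kfold(variants, lambda pid: pid, k=3, seed=2)
        seen = [v for _, test in folds for v in test]
        assert sorted(map(repr, seen)) == sorted(map(repr, variants))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(_variants("P1", 1, 1), lambda pid: pid, k=2)


class TestAlleleFrequencyFilter:
    def test_threshold_semantics(self):
        keep_low = VariantRecord("P", 1, "A", "V", allele_freq=0.169)
        drop_high = VariantRecord("P", 2, "A", "V", allele_freq=0.20)
        at_cut = VariantRecord("P", 3, "A", "V", allele_freq=0.17)
        no_af = VariantRecord("P", 4, "A", "V")
        kept = allele_frequency_filter([keep_low, drop_high, at_cut, no_af])
        assert kept == [keep_low, no_af]


class TestConfusionAndMetrics:
    def test_perfect_predictions(self):
        c = confusion([1, 1, 1, 0, 0], [1, 1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 2, 0, 0)
        r = metrics(c)
        assert (r.mcc, r.acc, r.sen, r.spe) == (1.0, 1.0, 1.0, 1.0)

    def test_all_disease_predictions(self):
        c = confusion(["disease"] * 5, [1, 0, 0, 1, 0])
        assert c.fp == 3 and c.fn == 0

    def test_hand_tallied_fixture(self):
        preds = ["disease", "neutral", "disease", "disease", "neutral", "neutral", "disease"]
        labels = [1, 1, 0, 1, 0, 1, 1]
        c = confusion(preds, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 1, 1, 2)

    def test_worked_confusion_table(self):
        r = metrics(ConfusionCounts(tp=2, tn=3, fp=1, fn=1))
        assert r.mcc == pytest.approx(5 / 12)
        assert r.acc == pytest.approx(5 / 7)
        assert r.sen == pytest.approx(2 / 3)
        assert r.spe == pytest.approx(3 / 4)
        assert r.ppv == pytest.approx(2 / 3)
        assert r.npv == pytest.approx(3 / 4)

    def test_degenerate_single_class_prediction(self):
        r = metrics(confusion([0, 0, 0], [1, 0, 1]))
        assert r.mcc == 0.0  # zero-denominator convention
        assert r.ppv is None  # undefined, reported missing rather than 0

    def test_mcc_invariant_under_class_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            a = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            b = metrics(ConfusionCounts(int(tn), int(tp), int(fn), int(fp)))
            assert a.mcc == pytest.approx(b.mcc)
            assert a.sen == pytest.approx(b.spe)
            assert a.ppv == pytest.approx(b.npv)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1, 0, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_pair_enumeration_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == 0.75  # 3 of 4 positive-negative pairs correctly ordered

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        a, _ = roc_auc(scores, labels)
        b, _ = roc_auc(np.exp(2 * scores) + 5, labels)
        assert a == pytest.approx(b)

    def test_matches_trapezoid_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            mine, _ = roc_auc(scores, labels)
            assert mine == pytest.approx(roc_auc_score(labels, scores))


class TestFprTools:
    def test_false_positive_rate(self):
        assert false_positive_rate([0] * 100) == 0.0
        assert false_positive_rate([1] * 10 + [0] * 90) == 0.10
        with pytest.raises(ValueError):
            false_positive_rate([])

    def test_raising_cutoff_never_raises_fpr(self, rng):
        from entprise import classify

        scores = rng.random(200)
        low = false_positive_rate(classify(scores, 0.45))
        high = false_positive_rate(classify(scores, 0.55))
        assert high <= low

    def test_collinear_pairs(self):
        slope, intercept, r = fpr_cross_regression([(1, 2), (2, 4), (3, 6)])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.random(8)
        y = 1.3 * x + 0.05 + rng.normal(0, 0.01, 8)
        slope, intercept, _ = fpr_cross_regression(list(zip(x, y)))
        A = np.column_stack([x, np.ones(8)])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(expected[0])
        assert intercept == pytest.approx(expected[1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fpr_cross_regression([(1, 2), (1, 3), (1, 4)])
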