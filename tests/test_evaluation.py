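import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psbinder.evaluation import (
    ConfusionMatrix,
    cross_validate,
    kfold_split,
    mann_whitney_auc,
    metrics_from_confusion,
    roc_auc,
)
from psbinder.svm import SVMConfig


class TestKfoldSplit:
    def test_balanced_tiny(self):
        y = [1, 0] * 5
        folds = kfold_split(y, k=5, seed=0)
        for f in folds:
            assert f.size == 2
            assert sorted(np.asarray(y)[f]) == [0, 1]

    def test_208_balanced_sizes(self):
        y = [1] * 104 + [0] * 104
        folds = kfold_split(y, k=5, seed=1)
        sizes = sorted(f.size for f in folds)
        assert sizes == [41, 41, 42, 42, 42]
        # stratification: class counts within each fold differ by <= 1
        for f in folds:
            npos = int(np.sum(np.asarray(y)[f]))
            assert abs(npos - (f.size - npos)) <= 1

    def test_union_covers_all_indices_once(self):
        y = [1] * 13 + [0] * 9
        folds = kfold_split(y, k=5, seed=3)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(22))

    def test_deterministic_given_seed(self):
        y = [1, 0] * 20
        a = kfold_split(y, seed=7)
        b = kfold_split(y, seed=7)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kfold_split([1, 0, 1], k=5)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_published_operating_point(self):
        # confusion counts reconstructed from the reported per-class rates
        # at 104 peptides per class
        m = metrics_from_confusion(ConfusionMatrix(tp=92, fp=15, tn=89, fn=12))
        assert m.sn == pytest.approx(0.8846, abs=5e-5)
        assert m.sp == pytest.approx(0.8558, abs=5e-5)
        assert m.acc == pytest.approx(0.8702, abs=5e-5)
        assert m.mcc == pytest.approx(0.7407, abs=5e-5)

    def test_total_inversion(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=10, tn=0, fn=10))
        assert m.acc == 0.0 and m.mcc == -1.0

    def test_zero_denominator_flagged(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=10, fn=10))
        assert m.mcc == 0.0 and m.mcc_undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_per_sample_tally(self, pairs):
        y_true = [int(t) for t, _ in pairs]
        y_pred = [int(p) for _, p in pairs]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        assert cm.total == len(pairs)
        acc_direct = np.mean(np.array(y_true) == np.array(y_pred))
        assert metrics_from_confusion(cm).acc == pytest.approx(acc_direct)

    @given(st.integers(1, 40), st.integers(0, 40),
           st.integers(1, 40), st.integers(0, 40))
    @settings(max_examples=100, deadline=None)
    def test_label_swap_symmetry(self, tp, fp, tn, fn):
        m = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))
        # swapping both labels and predictions exchanges TP<->TN, FP<->FN
        sw = metrics_from_confusion(ConfusionMatrix(tn, fn, tp, fp))
        assert sw.sn == pytest.approx(m.sp)
        assert sw.sp == pytest.approx(m.sn)
        assert sw.acc == pytest.approx(m.acc)
        assert sw.mcc == pytest.approx(m.mcc)  # MCC invariant under the swap


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1 for p in pos for q in neg if p > q)
    ties = sum(1 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ordering(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]

    def test_all_ties_is_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_three_point_hand_case(self):
        # pairs: (0.9 vs 0.7) concordant, (0.4 vs 0.7) discordant -> 1/2
        auc, _ = roc_auc([0.9, 0.7, 0.4], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @given(st.lists(st.tuples(st.integers(0, 10), st.booleans()),
                    min_size=4, max_size=50))
    @settings(max_examples=150, deadline=None)
    def test_trapezoid_equals_pair_counting(self, data):
        scores = [s / 10 for s, _ in data]
        labels = [int(l) for _, l in data]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        auc, _ = roc_auc(scores, labels)  # cross-checks internally too
        assert auc == pytest.approx(brute_force_auc(scores, labels))
        assert auc == pytest.approx(mann_whitney_auc(scores, labels))


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(3.0, 0.2, size=(25, 2)),
            rng.normal(-3.0, 0.2, size=(25, 2)),
        ])
        return X, np.array([1] * 25 + [0] * 25)

    def test_separable_everything_perfect(self, separable):
        X, y = separable
        rep = cross_validate(X, y, SVMConfig(c=8.0, g=0.5), seed=0)
        assert rep.acc == 1.0 and rep.mcc == 1.0 and rep.auc == 1.0
        assert rep.confusion.fp == 0 and rep.confusion.fn == 0

    def test_fold_average_close_to_pooled(self, separable):
        X, y = separable
        rep = cross_validate(X, y, SVMConfig(c=2.0, g=0.5), seed=1)
        assert abs(rep.acc - rep.pooled.acc) < 1 / 10  # n_min = 10 per fold

    def test_report_serializes(self, separable):
        X, y = separable
        rep = cross_validate(X, y, SVMConfig(c=2.0, g=0.5), seed=1)
        d = rep.to_dict()
        assert len(d["folds"]) == 5
        assert d["confusion"]["tp"] + d["confusion"]["fn"] == 25
        assert rep.roc_tsv().startswith("fpr\ttpr")

    def test_reproducible_given_seed(self, separable):
        X, y = separable
        a = cross_validate(X, y, SVMConfig(c=2.0, g=0.5), seed=4)
        b = cross_validate(X, y, SVMConfig(c=2.0, g=0.5), seed=4)
        assert a.to_json() == b.to_json()
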