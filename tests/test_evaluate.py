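import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perifw.evaluate import (ConfusionCounts, CvResult, classification_metrics,
                             confusion_counts, cross_validate, delong_compare,
                             kfold_partition, mann_whitney_auc, roc_and_auc,
                             round_metrics)
from perifw.patches import Patch, PatchSet

GBM, MET = "glioblastoma", "metastasis"


def _patchset(labels, subjects=None):
    subjects = subjects or [f"s{i}" for i in range(len(labels))]
    rng = np.random.default_rng(0)
    patches = [Patch(values=rng.random((16, 16)), origin=(0, 0, i),
                     subject_id=subjects[i], label=labels[i], map_kind="FW-VF")
               for i in range(len(labels))]
    return PatchSet(patches, "FW-VF")


class TestConfusion:
    def test_all_correct(self):
        c = confusion_counts([GBM] * 3 + [MET] * 2, [GBM] * 3 + [MET] * 2)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 2, 0, 0)

    def test_flipping_predictions_swaps_counts(self):
        true = [GBM, GBM, MET, MET, GBM]
        pred = [GBM, MET, MET, GBM, GBM]
        c = confusion_counts(pred, true)
        flipped = [MET if p == GBM else GBM for p in pred]
        cf = confusion_counts(flipped, true)
        assert (cf.tp, cf.fn) == (c.fn, c.tp)
        assert (cf.tn, cf.fp) == (c.fp, c.tn)

    def test_empty_vectors(self):
        c = confusion_counts([], [])
        assert c.total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_counts([GBM], [GBM, MET])


class TestMetrics:
    def test_printed_cohort_worked_example(self):
        """20 glioblastomas and 10 metastases with per-class recalls 95%
        and 90% give TP=19 FN=1 TN=9 FP=1, hence accuracy 93.3% -> 93."""
        m = classification_metrics(ConfusionCounts(tp=19, fn=1, tn=9, fp=1))
        assert m["accuracy"] == pytest.approx(93.33333333, abs=1e-6)
        assert m["sensitivity"] == pytest.approx(95.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert round_metrics(m) == {"accuracy": 93, "sensitivity": 95,
                                    "specificity": 90}

    def test_balanced_half_accuracy(self):
        m = classification_metrics(ConfusionCounts(5, 5, 5, 5))
        assert m["accuracy"] == pytest.approx(50.0)

    def test_perfect_counts(self):
        m = classification_metrics(ConfusionCounts(tp=7, fp=0, tn=3, fn=0))
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == \
            (100.0, 100.0, 100.0)

    def test_undefined_metric_is_none_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m["sensitivity"] is None
        assert m["specificity"] == 100.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(derandomize=True, max_examples=60)
    def test_accuracy_identity(self, tp, fp, tn, fn):
        """accuracy = (sens*P + spec*N) / (P + N) whenever all are defined."""
        if tp + fp + tn + fn == 0:
            return
        m = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        P, N = tp + fn, tn + fp
        if m["sensitivity"] is None or m["specificity"] is None:
            return
        lhs = m["accuracy"]
        rhs = (m["sensitivity"] * P + m["specificity"] * N) / (P + N)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestKfold:
    def test_equal_fold_sizes(self):
        ps = _patchset([GBM, MET] * 50)
        folds = kfold_partition(ps, k=5, seed=0)
        assert [len(f) for f in folds] == [20] * 5

    def test_disjoint_and_complete(self):
        ps = _patchset([GBM, MET] * 26)
        folds = kfold_partition(ps, k=5, seed=1)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(len(ps)))

    def test_deterministic(self):
        ps = _patchset([GBM, MET] * 20)
        a = kfold_partition(ps, k=5, seed=2)
        b = kfold_partition(ps, k=5, seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_subject_level_keeps_subjects_together(self):
        labels = [GBM, MET] * 20
        subjects = [f"s{i // 4}" for i in range(40)]   # 4 patches/subject
        ps = _patchset(labels, subjects)
        folds = kfold_partition(ps, k=5, seed=0, level="subject")
        sid = ps.subject_ids
        seen = {}
        for fi, fold in enumerate(folds):
            for s in set(sid[fold]):
                assert seen.setdefault(s, fi) == fi

    def test_k_exceeding_units_rejected(self):
        ps = _patchset([GBM, MET])
        with pytest.raises(ValueError, match="exceeds"):
            kfold_partition(ps, k=5, seed=0)


class _ConstantClassifier:
    """Always predicts glioblastoma, the modal strategy on a 50/50 set."""

    def fit(self, ps):
        pass

    def predict_proba(self, ps):
        return np.tile([1.0, 0.0], (len(ps), 1))


class _OracleClassifier:
    def fit(self, ps):
        pass

    def predict_proba(self, ps):
        return np.array([[1.0, 0.0] if l == GBM else [0.0, 1.0]
                         for l in ps.labels])


class TestCrossValidate:
    def test_constant_classifier_scores_chance_on_balanced_set(self):
        ps = _patchset([GBM, MET] * 30)
        cv = cross_validate(ps, lambda fold: _ConstantClassifier(), k=5, seed=0)
        assert cv.mean_metrics["accuracy"] == pytest.approx(50.0, abs=10.0)

    def test_oracle_classifier_is_perfect(self):
        ps = _patchset([GBM, MET] * 30)
        cv = cross_validate(ps, lambda fold: _OracleClassifier(), k=5, seed=0)
        assert cv.mean_metrics["accuracy"] == 100.0
        assert len(cv.fold_metrics) == 5

    def test_mean_equals_average_of_folds(self):
        ps = _patchset([GBM, MET] * 25)
        cv = cross_validate(ps, lambda fold: _OracleClassifier(), k=5, seed=1)
        for key in ("accuracy", "sensitivity", "specificity"):
            assert cv.mean_metrics[key] == pytest.approx(
                np.mean([m[key] for m in cv.fold_metrics]))


class TestCvProtocol:
    def test_patch_level_cv_not_below_subject_level(self):
        """Patch-level folds let one subject's patches span train and
        validation; with a weak class effect but strong per-subject
        intensity signatures, that leakage inflates patch-level CV above
        grouped subject-level CV — the direction this test pins down."""
        from perifw.texture import RandomForestConfig, TextureRfClassifier
        rng = np.random.default_rng(0)
        patches = []
        for s in range(20):
            label = GBM if s % 2 == 0 else MET
            offset = rng.uniform(0.25, 0.75)          # subject signature
            effect = 0.01 if label == GBM else -0.01  # weak class effect
            for i in range(15):
                vals = np.clip(offset + effect
                               + 0.01 * rng.standard_normal((16, 16)), 0, 1)
                patches.append(Patch(values=vals, origin=(0, 0, i),
                                     subject_id=f"s{s}", label=label,
                                     map_kind="FW-VF"))
        ps = PatchSet(patches, "FW-VF")

        def run(level):
            cv = cross_validate(
                ps,
                lambda fold: TextureRfClassifier(
                    "radiomic",
                    rf_config=RandomForestConfig(n_estimators=100, seed=fold)),
                k=5, seed=0, level=level)
            return cv.mean_metrics["accuracy"]

        assert run("patch") >= run("subject")


def _pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney: enumerate every positive x negative pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_and_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert roc.auc == 1.0

    def test_identical_scores_give_half(self):
        roc = roc_and_auc([0.5] * 6, [True, False] * 3)
        assert roc.auc == 0.5

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = rng.random(40) > 0.5
        roc = roc_and_auc(scores, labels)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_auc([0.1, 0.2], [True, True])

    @given(st.data())
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_auc_equals_exhaustive_pair_counting(self, data):
        n = data.draw(st.integers(4, 30))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            return
        scores = data.draw(st.lists(
            st.integers(0, 10), min_size=n, max_size=n))  # ints force ties
        scores = [s / 10 for s in scores]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            _pair_count_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_on_random_instance(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.random(50) > 0.4
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


def _delong_oracle(sa, sb, labels):
    """Direct structural-components computation on a tiny instance."""
    pos = np.asarray(labels, bool)
    m, n = pos.sum(), (~pos).sum()

    def placements(s):
        sp, sn = s[pos], s[~pos]
        v10 = np.array([np.mean((p > sn) + 0.5 * (p == sn)) for p in sp])
        v01 = np.array([np.mean((sp > q) + 0.5 * (sp == q)) for q in sn])
        return v10, v01

    v10a, v01a = placements(np.asarray(sa, float))
    v10b, v01b = placements(np.asarray(sb, float))
    auc_a, auc_b = v10a.mean(), v10b.mean()

    def cov(x, y):
        return ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)

    var = (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m + \
          (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    return auc_a, auc_b, var


class TestDeLong:
    def test_self_comparison_p_is_one(self):
        scores = [0.1, 0.7, 0.4, 0.9, 0.3, 0.6]
        labels = [False, True, False, True, False, True]
        out = delong_compare(scores, scores, labels)
        assert out["diff"] == 0.0
        assert out["p"] == 1.0

    def test_label_inversion_maps_auc(self):
        scores = np.array([0.1, 0.7, 0.4, 0.9, 0.3, 0.6])
        labels = np.array([False, True, False, True, False, True])
        a = mann_whitney_auc(scores, labels)
        assert mann_whitney_auc(scores, ~labels) == pytest.approx(1.0 - a)

    def test_variance_matches_brute_force_oracle_n6(self):
        sa = [0.9, 0.8, 0.35, 0.7, 0.2, 0.1]
        sb = [0.6, 0.9, 0.4, 0.3, 0.5, 0.2]
        labels = [True, True, True, False, False, False]
        out = delong_compare(sa, sb, labels)
        auc_a, auc_b, var = _delong_oracle(sa, sb, labels)
        assert out["auc_a"] == pytest.approx(auc_a, abs=1e-12)
        assert out["auc_b"] == pytest.approx(auc_b, abs=1e-12)
        z_oracle = (auc_a - auc_b) / np.sqrt(var)
        assert out["z"] == pytest.approx(z_oracle, abs=1e-10)

    def test_zero_variance_with_different_aucs_rejected(self):
        # constant per-class placements but different AUCs cannot happen
        # with m = n = 1 unless scores differ; force the degenerate path
        sa = [0.9, 0.1]
        sb = [0.1, 0.9]
        labels = [True, False]
        with pytest.raises(ValueError, match="zero variance"):
            delong_compare(sa, sb, labels)

    def test_unpaired_scores_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_compare([0.1, 0.2], [0.3], [True, False])
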