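import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dilitext as dt
from dilitext.evaluation import ConfusionCounts, score_metrics


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def oracle_metrics(tp, fp, tn, fn):
    total = tp + fp + tn + fn
    out = {"ACC": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    out["precision"] = tp / (tp + fp) if tp + fp else float("nan")
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (fn + tn))
    out["MCC"] = (tp * tn - fp * fn) / den if den else float("nan")
    return out


def oracle_auc(scores, labels):
    """O(n^2) pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_confusion(scores, labels, t):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = 1 if s >= t else 0
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and not y:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


# ---------------------------------------------------------------------------
# fold plans


class TestFoldPlan:
    def test_exact_stratification(self):
        labels = np.array([1] * 35 + [0] * 65)
        plan = dt.make_fold_plan(labels, k=5, R=3, seed=0)
        for r in range(3):
            for f in range(5):
                _, va = plan.split(r, f)
                assert (labels[va] == 1).sum() == 7
                assert (labels[va] == 0).sum() == 13

    def test_deterministic(self):
        labels = np.array([1] * 30 + [0] * 70)
        p1 = dt.make_fold_plan(labels, seed=42)
        p2 = dt.make_fold_plan(labels, seed=42)
        assert np.array_equal(p1.assignment, p2.assignment)

    def test_each_doc_validated_once_per_set(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(173) < 0.4).astype(int)
        plan = dt.make_fold_plan(labels, k=5, R=10, seed=1)
        # every document appears in exactly one fold per set -> validated
        # exactly R times in total
        validated = np.zeros(173, dtype=int)
        for r in range(10):
            for f in range(5):
                _, va = plan.split(r, f)
                validated[va] += 1
            assert sorted(np.concatenate(
                [plan.split(r, f)[1] for f in range(5)]
            )) == list(range(173))
        assert (validated == 10).all()

    def test_stratification_within_one_document(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(101) < 0.35).astype(int)
        plan = dt.make_fold_plan(labels, k=5, R=4, seed=5)
        pos_frac = labels.mean()
        for r in range(4):
            for f in range(5):
                _, va = plan.split(r, f)
                n_pos = int(labels[va].sum())
                assert abs(n_pos - pos_frac * len(va)) <= 1

    def test_small_class_errors(self):
        labels = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ValueError, match="fewer than k"):
            dt.make_fold_plan(labels, k=5)

    def test_jaccard_diagnostic_bounded(self):
        labels = np.array([1] * 40 + [0] * 60)
        plan = dt.make_fold_plan(labels, k=5, R=3, seed=2)
        assert 0.0 <= plan.max_fold_jaccard() < 1.0


# ---------------------------------------------------------------------------
# metric primitives


class TestConfusion:
    def test_basic(self):
        c = dt.confusion([0.9, 0.2], [1, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_tie_rounds_up(self):
        c = dt.confusion([0.5], [0], 0.5)
        assert c.FP == 1

    def test_random_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        for t in (0.2, 0.5, 0.9):
            c = dt.confusion(scores, labels, t)
            assert (c.TP, c.FP, c.TN, c.FN) == oracle_confusion(scores, labels, t)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dt.confusion([0.5, 0.5], [1])


class TestMetricsFromConfusion:
    def test_perfect(self):
        m = dt.metrics_from_confusion(ConfusionCounts(TP=10, FP=0, TN=10, FN=0))
        assert all(m[k] == 1.0 for k in m)

    def test_chance(self):
        m = dt.metrics_from_confusion(ConfusionCounts(TP=5, FP=5, TN=5, FN=5))
        assert m["MCC"] == 0.0
        assert m["ACC"] == 0.5

    def test_zero_denominator_is_nan(self):
        m = dt.metrics_from_confusion(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
        assert math.isnan(m["precision"])
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["MCC"])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dt.metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))

    def test_thousand_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fp + tn + fn == 0:
                continue
            got = dt.metrics_from_confusion(ConfusionCounts(tp, fp, tn, fn))
            want = oracle_metrics(int(tp), int(fp), int(tn), int(fn))
            for k in want:
                if math.isnan(want[k]):
                    assert math.isnan(got[k])
                else:
                    assert got[k] == pytest.approx(want[k], abs=1e-12)


class TestRocAuc:
    def test_perfect_sorting(self):
        scores = [0.9] * 10 + [0.1] * 10
        labels = [1] * 10 + [0] * 10
        assert dt.roc_auc(scores, labels) == 1.0

    def test_all_tied(self):
        assert dt.roc_auc([0.5] * 20, [1] * 10 + [0] * 10) == 0.5

    def test_random_oracle(self):
        rng = np.random.default_rng(13)
        scores = np.round(rng.random(300), 2)  # rounding forces ties
        labels = (rng.random(300) < 0.5).astype(int)
        assert dt.roc_auc(scores, labels) == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )

    def test_reversal_complement(self):
        rng = np.random.default_rng(17)
        scores = rng.random(100)  # continuous, tie-free a.s.
        labels = (rng.random(100) < 0.5).astype(int)
        a = dt.roc_auc(scores, labels)
        b = dt.roc_auc(-scores, labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            dt.roc_auc([0.1, 0.9], [1, 1])

    def test_curve_points(self):
        auc, curve = dt.roc_auc([0.9, 0.1], [1, 0], return_curve=True)
        assert auc == 1.0
        assert curve.iloc[0]["fpr"] == 0.0 and curve.iloc[-1]["tpr"] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(4, 30))
        # round to 3 decimals so the transform cannot collapse distinct
        # scores into ties through float rounding
        scores = np.round(
            data.draw(
                st.lists(
                    st.floats(0, 1, allow_nan=False), min_size=n, max_size=n
                )
            ),
            3,
        )
        labels = np.array(data.draw(st.lists(st.sampled_from([0, 1]),
                                             min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            return
        a = dt.roc_auc(scores, labels)
        b = dt.roc_auc(np.exp(3 * scores), labels)  # strictly increasing map
        assert a == pytest.approx(b, abs=1e-12)


class TestRmse:
    def test_exact_match_zero(self):
        assert dt.rmse([0.0, 1.0], [0, 1]) == 0.0

    def test_all_half(self):
        assert dt.rmse([0.5] * 8, [1, 0] * 4) == 0.5

    def test_random_oracle(self):
        rng = np.random.default_rng(19)
        s = rng.random(50)
        y = (rng.random(50) < 0.5).astype(int)
        want = math.sqrt(sum((a - b) ** 2 for a, b in zip(s, y)) / 50)
        assert dt.rmse(s, y) == pytest.approx(want, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dt.rmse([], [])


class TestProfitAnalysis:
    def test_monotonicity(self):
        rng = np.random.default_rng(23)
        scores = rng.random(150)
        labels = (rng.random(150) < 0.4).astype(int)
        table = dt.profit_analysis(scores, labels)
        assert table["FN"].is_monotonic_increasing
        assert table["FP"].is_monotonic_decreasing
        assert table["n_predicted_positive"].is_monotonic_decreasing

    def test_threshold_zero(self):
        scores = [0.1, 0.9, 0.4]
        labels = [1, 0, 1]
        table = dt.profit_analysis(scores, labels, thresholds=(0.0,))
        assert table.iloc[0]["FN"] == 0
        assert table.iloc[0]["n_predicted_positive"] == 3

    def test_equals_repeated_confusion(self):
        rng = np.random.default_rng(29)
        scores = rng.random(80)
        labels = (rng.random(80) < 0.5).astype(int)
        ts = (0.1, 0.3, 0.5, 0.7, 0.9)
        table = dt.profit_analysis(scores, labels, ts)
        for row, t in zip(table.itertuples(), ts):
            c = dt.confusion(scores, labels, t)
            assert (row.FN, row.FP) == (c.FN, c.FP)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            dt.profit_analysis([0.5], [1], thresholds=(1.5,))

    @settings(max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        labels_seed=st.integers(0, 10_000),
    )
    def test_monotonicity_property(self, scores, labels_seed):
        rng = np.random.default_rng(labels_seed)
        labels = (rng.random(len(scores)) < 0.5).astype(int)
        table = dt.profit_analysis(scores, labels)
        assert table["FN"].is_monotonic_increasing
        assert table["FP"].is_monotonic_decreasing


class TestConsistencyReport:
    def test_fully_consistent(self):
        rep = dt.consistency_report([0.95, 0.05], [1, 0])
        assert rep.overall == 1.0
        bins = rep.bins
        assert bins.loc[9, "fraction"] == 1.0
        assert bins.loc[0, "fraction"] == 1.0

    def test_inconsistent_bin(self):
        rep = dt.consistency_report([0.55], [0])
        assert rep.overall == 0.0
        assert rep.bins.loc[5, "count"] == 1
        assert rep.bins.loc[5, "fraction"] == 0.0

    def test_overall_equals_confusion_complement(self):
        rng = np.random.default_rng(31)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        rep = dt.consistency_report(scores, labels)
        c = dt.confusion(scores, labels, 0.5)
        assert rep.overall == pytest.approx(1 - (c.FN + c.FP) / 200, abs=1e-12)

    def test_overall_is_count_weighted_bin_mean(self):
        rng = np.random.default_rng(37)
        scores = rng.random(300)
        labels = (rng.random(300) < 0.5).astype(int)
        rep = dt.consistency_report(scores, labels)
        bins = rep.bins
        weighted = (bins["consistent"].sum()) / bins["count"].sum()
        assert rep.overall == pytest.approx(weighted, abs=1e-12)

    def test_u_shape_on_calibrated_scores(self):
        # well-calibrated scores: labels drawn Bernoulli(score)
        rng = np.random.default_rng(41)
        scores = rng.random(5000)
        labels = (rng.random(5000) < scores).astype(int)
        rep = dt.consistency_report(scores, labels)
        extreme = (rep.bins.loc[0, "fraction"] + rep.bins.loc[9, "fraction"]) / 2
        middle = (rep.bins.loc[4, "fraction"] + rep.bins.loc[5, "fraction"]) / 2
        assert extreme > middle


# ---------------------------------------------------------------------------
# cross-validation


class TestCrossValidate:
    def test_separable_corpus_auc(self, toy_data):
        plan = dt.make_fold_plan(toy_data["labels"], k=5, R=2, seed=11)
        oof, report = dt.cross_validate(
            toy_data["dtm"], toy_data["labels"], dt.BoosterConfig(seed=11), plan
        )
        assert report.mean("AUC") >= 0.9
        assert not np.isnan(oof).any()

    def test_permuted_labels_null(self, toy_data):
        rng = np.random.default_rng(43)
        perm = rng.permutation(toy_data["labels"])
        plan = dt.make_fold_plan(perm, k=5, R=3, seed=43)
        _, report = dt.cross_validate(
            toy_data["dtm"], perm, dt.BoosterConfig(seed=43), plan
        )
        assert 0.35 <= report.mean("AUC") <= 0.65

    def test_training_beats_validation(self):
        # overfitting direction: across >= 10 seeds, training AUC mean above
        # validation AUC mean on every run
        import dilitext as dt_

        wins = 0
        for seed in range(10):
            spec = dt_.GeneratorSpec(
                n_docs=80, vocabulary_size=30, n_signal_terms=4,
                rate_ratio=2.0, mean_doc_length=60.0, n_phrases=4, seed=seed,
            )
            dct, rec = dt_.make_toy_dictionary(spec)
            docs = dt_.simulate_corpus(spec, dct, rec)
            labels = np.array([d.label for d in docs])
            w = dt_.tfidf_weight(
                dt_.build_count_matrix(dt_.extract_corpus(docs, dct, rec))
            )
            plan = dt_.make_fold_plan(labels, k=4, R=1, seed=seed)
            _, rep = dt_.cross_validate(w, labels, dt_.BoosterConfig(seed=seed), plan)
            if rep.mean("AUC", "training") >= rep.mean("AUC", "validation"):
                wins += 1
        assert wins >= 9

    def test_plan_mismatch_errors(self, toy_data):
        labels = np.array([1] * 30 + [0] * 30)
        plan = dt.make_fold_plan(labels, k=3, R=1, seed=0)
        with pytest.raises(ValueError, match="cover"):
            dt.cross_validate(
                toy_data["dtm"], toy_data["labels"], plan=plan
            )


# ---------------------------------------------------------------------------
# model screening


@pytest.fixture(scope="module")
def screening(toy_data):
    return dt.screen_models(
        toy_data["dtm"], toy_data["labels"], k=4, L=3, seed=11
    )


class TestScreenModels:
    def test_all_families_beat_chance(self, screening):
        assert (screening["validation_auc"] > 0.8).all()

    def test_ensembles_beat_single_tree(self, screening):
        auc = dict(zip(screening["family"], screening["validation_auc"]))
        assert auc["boosted_tree"] >= auc["decision_tree"]
        assert auc["random_forest"] >= auc["decision_tree"]

    def test_null_labels_near_half(self, toy_data):
        rng = np.random.default_rng(47)
        perm = rng.permutation(toy_data["labels"])
        table = dt.screen_models(
            toy_data["dtm"], perm, k=4, L=3, seed=47,
            families=["decision_tree", "svm"],
        )
        assert ((table["validation_auc"] - 0.5).abs() <= 0.15).all()

    def test_deterministic(self, toy_data, screening):
        again = dt.screen_models(
            toy_data["dtm"], toy_data["labels"], k=4, L=3, seed=11
        )
        assert again.equals(screening)

    def test_unknown_family_errors(self, toy_data):
        with pytest.raises(ValueError, match="unknown model families"):
            dt.screen_models(
                toy_data["dtm"], toy_data["labels"], families=["bogus"]
            )


def test_score_metrics_bounds(toy_data, toy_model):
    p = toy_model.predict_proba(toy_data["dtm"].weights)
    m = score_metrics(p, toy_data["labels"])
    for k in ("ACC", "AUC", "sensitivity", "specificity", "precision", "RMSE"):
        assert 0.0 <= m[k] <= 1.0
    assert -1.0 <= m["MCC"] <= 1.0


def test_corpus_summary():
    s = dt.corpus_summary([1] * 238 + [0] * 440)
    assert s["n_docs"] == 678
    assert s["positive_percent"] == 35
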