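"""Vectorization, training, recall-targeted calibration, evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenodefminer.classifiers import (
    ALGORITHMS,
    AbstractVectorizer,
    EmptyVocabularyError,
    OperatingPoint,
    SplitConfig,
    VectorizerConfig,
    apply_threshold,
    calibrate_threshold,
    evaluate,
    evaluate_weighted,
    load_model,
    metrics_at_recall,
    predict_scores,
    save_model,
    split_train_test,
    train_classifier,
    vectorize_abstracts,
)
from phenodefminer.corpus_io import AbstractDocument


def _doc(pmid, text, label=None):
    return AbstractDocument(pmid=pmid, title="", abstract_text=text, label=label)


# ---------------------------------------------------------------------------
# Independent oracles


def tfidf_oracle(doc_texts, ngram_max, words_to_keep):
    """Hand-rolled bag-of-n-grams TF-IDF with the documented transforms.

    Tokens: maximal runs of word characters, lowercased; grams joined by
    spaces; vocabulary = top ``words_to_keep`` grams by total frequency
    (ties lexicographic); cell = log(1+count) * log(N/df).
    """
    import re

    token_re = re.compile(r"[^\W_]+(?:-[^\W_]+)*")
    all_grams = []
    for text in doc_texts:
        tokens = token_re.findall(text.lower())
        grams = []
        for n in range(1, ngram_max + 1):
            for i in range(len(tokens) - n + 1):
                grams.append(" ".join(tokens[i : i + n]))
        all_grams.append(grams)
    totals = {}
    for grams in all_grams:
        for g in grams:
            totals[g] = totals.get(g, 0) + 1
    vocab = sorted(sorted(totals), key=lambda g: -totals[g])[:words_to_keep]
    vocab = sorted(vocab)
    col = {g: j for j, g in enumerate(vocab)}
    N = len(doc_texts)
    df = [sum(1 for grams in all_grams if g in grams) for g in vocab]
    X = np.zeros((N, len(vocab)))
    for i, grams in enumerate(all_grams):
        for g in grams:
            if g in col:
                X[i, col[g]] += 1
    tf = np.log1p(X)
    idf = np.array([math.log(N / d) for d in df])
    return tf * idf, vocab


def sweep_oracle(scores, labels, target):
    """Exhaustive sweep over all distinct cutoffs (plus above-max)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cutoffs = sorted(set(scores.tolist()))
    cutoffs.append(cutoffs[-1] + 1.0)
    rows = []
    for t in cutoffs:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        r = tp / (tp + fn) if tp + fn else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        rows.append((t, r, p))
    feasible = [row for row in rows if row[1] >= target]
    if not feasible:
        return None
    t_star = max(feasible, key=lambda row: row[0])
    same = [row for row in feasible if row[1] == t_star[1]]
    return max(same, key=lambda row: (row[2], row[0]))


# ---------------------------------------------------------------------------
# Vectorizer


class TestVectorizer:
    CFG = VectorizerConfig(stemmer="none", stopword_list="none", words_to_keep=50)

    def test_matches_hand_computed_tfidf(self):
        texts = [
            "asthma cases were defined by codes",
            "codes and labs defined the cohort",
            "generic cohort description text",
        ]
        docs = [_doc(f"p{i}", t) for i, t in enumerate(texts)]
        X, vocab, _ = vectorize_abstracts(docs, self.CFG)
        X_exp, vocab_exp = tfidf_oracle(texts, ngram_max=3, words_to_keep=50)
        assert vocab == vocab_exp
        np.testing.assert_allclose(X, X_exp, rtol=1e-12)

    def test_stopword_only_corpus_raises(self):
        docs = [_doc("p0", "the of and to in")]
        with pytest.raises(EmptyVocabularyError, match="stopword"):
            vectorize_abstracts(docs, VectorizerConfig())

    def test_trigram_enumeration(self):
        _, vocab, _ = vectorize_abstracts([_doc("p0", "a b c d")], self.CFG)
        assert "a b c" in vocab and "b c d" in vocab

    def test_vocabulary_never_grows_from_test_documents(self):
        train = [_doc(f"p{i}", f"term{i} shared words here") for i in range(5)]
        test = [_doc("q0", "entirely novel vocabulary elsewhere")]
        vec = AbstractVectorizer(self.CFG)
        vec.fit(train)
        vocab_before = dict(vec.vocabulary_)
        Xt = vec.transform(test)
        assert vec.vocabulary_ == vocab_before
        assert Xt.shape == (1, len(vocab_before))
        assert Xt.sum() == 0.0  # no overlap with training vocabulary

    def test_truncation_tie_break_lexicographic(self):
        cfg = VectorizerConfig(
            stemmer="none", stopword_list="none", words_to_keep=2, ngram_max=1
        )
        # zebra/apple/mango all appear twice: lexicographic keeps apple, mango
        docs = [_doc("p0", "zebra apple mango"), _doc("p1", "mango apple zebra")]
        _, vocab, _ = vectorize_abstracts(docs, cfg)
        assert vocab == ["apple", "mango"]

    def test_stemming_merges_inflections(self):
        cfg = VectorizerConfig(stopword_list="none", words_to_keep=50, ngram_max=1)
        _, vocab, _ = vectorize_abstracts(
            [_doc("p0", "classified classify classifying")], cfg
        )
        assert len(vocab) == 1


# ---------------------------------------------------------------------------
# Splitting


class TestSplit:
    def _records(self, n_pos, n_neg):
        return [_doc(f"p{i}", "x", label=1) for i in range(n_pos)] + [
            _doc(f"n{i}", "x", label=0) for i in range(n_neg)
        ]

    def test_70_30_partition(self):
        train, test = split_train_test(self._records(60, 40), SplitConfig(seed=0))
        assert (len(train), len(test)) == (70, 30)
        assert {d.pmid for d in train}.isdisjoint({d.pmid for d in test})

    def test_same_seed_identical(self):
        records = self._records(30, 30)
        a = split_train_test(records, SplitConfig(seed=5))
        b = split_train_test(records, SplitConfig(seed=5))
        assert [d.pmid for d in a[0]] == [d.pmid for d in b[0]]

    def test_stratified_counts(self):
        train, _ = split_train_test(self._records(60, 40), SplitConfig(seed=1))
        n_pos = sum(1 for d in train if d.label == 1)
        assert abs(n_pos - 42) <= 1
        assert abs((len(train) - n_pos) - 28) <= 1

    def test_single_class_stratified_raises(self):
        with pytest.raises(ValueError, match="two classes"):
            split_train_test(self._records(10, 0), SplitConfig())


# ---------------------------------------------------------------------------
# Training & scoring


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X_pos = rng.normal(3.0, 0.3, size=(n // 2, 2))
    X_neg = rng.normal(-3.0, 0.3, size=(n // 2, 2))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    return X, y


class TestTraining:
    @pytest.mark.parametrize("algorithm", ["svm", "logistic_regression"])
    def test_separable_training_accuracy(self, algorithm):
        X, y = _separable()
        model = train_classifier(X, y, algorithm)
        assert evaluate(model.predict(X), y).accuracy == 1.0

    def test_single_class_raises(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, [1, 1, 1, 1, 1], "svm")

    def test_non_finite_raises(self):
        X, y = _separable(10)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_classifier(X, y, "svm")

    def test_unknown_algorithm(self):
        X, y = _separable(10)
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_classifier(X, y, "random_forest")

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_scores_shape_determinism_and_order(self, algorithm):
        X, y = _separable()
        model = train_classifier(X, y, algorithm)
        scores = predict_scores(model, X[:5])
        assert scores.shape == (5,)
        np.testing.assert_array_equal(scores, predict_scores(model, X[:5]))
        # duplicated rows, identical scores
        dup = predict_scores(model, np.vstack([X[0], X[0]]))
        assert dup[0] == dup[1]
        # descending scores put positives first on the separable set
        order = np.argsort(-predict_scores(model, X))
        assert set(y[order][: np.sum(y)]) == {1}

    def test_dimension_mismatch_names_width(self):
        X, y = _separable()
        model = train_classifier(X, y, "svm")
        with pytest.raises(ValueError, match="expected 2"):
            model.scores(np.ones((3, 5)))

    def test_save_load_round_trip(self, tmp_path):
        X, y = _separable()
        model = train_classifier(X, y, "logistic_regression")
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(back.scores(X), model.scores(X))


# ---------------------------------------------------------------------------
# Calibration


class TestCalibration:
    def test_perfectly_separated(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        op = calibrate_threshold(scores, labels, 0.95)
        assert op.achieved_recall == 1.0
        assert op.achieved_precision == 1.0
        np.testing.assert_array_equal(apply_threshold(scores, op), labels)

    def test_target_zero_allows_empty_predictions(self):
        op = calibrate_threshold([0.3, 0.7], [0, 1], target_recall=0.0)
        assert op.threshold > 0.7
        assert op.achieved_recall == 0.0  # no division error

    def test_no_positives_raises(self):
        with pytest.raises(ValueError, match="positive"):
            calibrate_threshold([0.1, 0.2], [0, 0], 0.95)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = np.round(rng.normal(size=n), 2)  # force score ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        target = float(rng.choice([0.0, 0.5, 0.8, 0.9, 0.95, 1.0]))
        op = calibrate_threshold(scores, labels, target)
        expected = sweep_oracle(scores, labels, target)
        assert expected is not None and op.reachable
        t, r, p = expected
        assert op.threshold == pytest.approx(t)
        assert op.achieved_recall == pytest.approx(r)
        assert op.achieved_precision == pytest.approx(p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_recall_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() == 0:
            labels[0] = 1
        recalls = []
        for t in np.sort(np.unique(scores)):
            pred = (scores >= t).astype(int)
            recalls.append(evaluate(pred, labels).recall)
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))


# ---------------------------------------------------------------------------
# Evaluation


class TestEvaluate:
    def test_all_correct(self):
        r = evaluate([1, 0, 1], [1, 0, 1])
        assert (r.accuracy, r.precision, r.recall, r.f_measure) == (1, 1, 1, 1)

    def test_confusion_example(self):
        # TP=3, FP=1, FN=1, TN=5
        pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        true = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        r = evaluate(pred, true)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.accuracy == pytest.approx(0.8)
        assert r.f_measure == pytest.approx(0.75)

    def test_zero_denominator_convention(self):
        r = evaluate([0, 0, 0], [1, 0, 1])
        assert (r.precision, r.recall, r.f_measure) == (0.0, 0.0, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate([1], [1, 0])

    def test_metrics_bounded_and_f_below_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pred = rng.integers(0, 2, 15)
            true = rng.integers(0, 2, 15)
            r = evaluate(pred, true)
            for v in (r.accuracy, r.precision, r.recall, r.f_measure):
                assert 0.0 <= v <= 1.0
            assert r.f_measure <= max(r.precision, r.recall) + 1e-12

    def test_weighted_variant_accuracy_matches(self):
        pred = [1, 0, 1, 0, 0]
        true = [1, 1, 1, 0, 0]
        assert evaluate_weighted(pred, true).accuracy == evaluate(pred, true).accuracy


class TestMetricsAtRecall:
    def test_separable_all_ones(self):
        scores = [0.9, 0.8, 0.1, 0.05]
        labels = [1, 1, 0, 0]
        report, op = metrics_at_recall(scores, labels, 0.95)
        assert report.f_measure == 1.0 and op.achieved_recall == 1.0

    def test_compositional_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        report, op = metrics_at_recall(scores, labels, 0.9)
        direct = evaluate(apply_threshold(scores, calibrate_threshold(scores, labels, 0.9)), labels)
        assert report == direct
        assert report.recall == op.achieved_recall
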