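import numpy as np
import pytest

from mirhairpin import (
    HairpinClassifier,
    HairpinFeaturizer,
    cross_validate,
    generate_synthetic_hairpins,
    load_model,
    predict_sequences,
    save_model,
    train,
)
from mirhairpin.model import assign_folds


def separable_data(n=60, d=8, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    X[y == 1, 0] += gap
    return X, y


class TestHairpinClassifier:
    def test_separable_data_fits_perfectly(self):
        X, y = separable_data()
        model = HairpinClassifier(C=1.0, gamma="scale").fit(X, y)
        assert (model.predict(X) == y).all()

    def test_training_deterministic_under_seed(self):
        X, y = separable_data(seed=3)
        a = HairpinClassifier(random_state=1).fit(X, y).predict(X)
        b = HairpinClassifier(random_state=1).fit(X, y).predict(X)
        assert (a == b).all()

    def test_random_forest_backend(self):
        X, y = separable_data(seed=5)
        model = HairpinClassifier(algorithm="random_forest", n_estimators=50,
                                  random_state=0).fit(X, y)
        assert (model.predict(X) == y).all()
        assert np.all(np.sign(model.decision_function(X[y == 1])) >= 0)

    def test_constant_feature_scales_to_zero(self):
        X, y = separable_data(seed=7)
        X[:, 3] = 2.5
        model = HairpinClassifier(C=1.0, gamma="scale").fit(X, y)
        scaled = model._scale(X)
        assert (scaled[:, 3] == 0).all()
        assert scaled.min() >= -1.0 and scaled.max() <= 1.0

    def test_feature_subset_by_name(self):
        from mirhairpin import FEATURE_NAMES

        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 54))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X[y == 1, 0] += 8.0
        model = HairpinClassifier(
            C=1.0, gamma="scale", feature_names=[FEATURE_NAMES[0], FEATURE_NAMES[9]]
        ).fit(X, y)
        assert model.n_features_in_ == 2
        assert (model.predict(X) == y).all()

    def test_grid_search_records_best_params(self):
        X, y = separable_data(n=40, seed=9)
        model = HairpinClassifier(random_state=0).fit(X, y)
        assert set(model.best_params_) == {"C", "gamma"}

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            HairpinClassifier(algorithm="nope").fit(*separable_data())

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ValueError):
            HairpinClassifier().fit(X, np.ones(len(X), dtype=int))


class TestFoldAssignment:
    def test_stratified_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        ids = [f"r{k}" for k in range(103)]
        y = (rng.random(103) < 0.3).astype(int)
        fold = assign_folds(ids, y, folds=5, seed=4)
        for cls in (0, 1):
            sizes = [np.sum((fold == f) & (y == cls)) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_assignment_order_invariant(self):
        ids = [f"r{k}" for k in range(40)]
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        fold = assign_folds(ids, y, folds=5, seed=1)
        perm = np.random.default_rng(2).permutation(40)
        fold_permuted = assign_folds([ids[i] for i in perm], y[perm], folds=5, seed=1)
        by_id = dict(zip(ids, fold))
        for k, i in enumerate(perm):
            assert fold_permuted[k] == by_id[ids[i]]

    def test_class_smaller_than_fold_count_rejected(self):
        ids = [f"r{k}" for k in range(10)]
        y = np.r_[np.ones(3, int), np.zeros(7, int)]
        with pytest.raises(ValueError):
            assign_folds(ids, y, folds=5, seed=0)


class TestCrossValidate:
    def test_pooled_counts_conserve_class_totals(self):
        X, y = separable_data(n=80, seed=13)
        ids = [f"r{k}" for k in range(len(y))]
        counts, report = cross_validate(
            X, y, ids, estimator=HairpinClassifier(C=1.0, gamma="scale"), seed=5
        )
        assert counts.tp + counts.fn == int(y.sum())
        assert counts.tn + counts.fp == int((1 - y).sum())
        assert report.balanced_acc > 90.0  # separable

    def test_reproducible_under_seed(self):
        X, y = separable_data(n=50, gap=1.0, seed=17)
        ids = [f"r{k}" for k in range(len(y))]
        kwargs = dict(estimator=HairpinClassifier(C=1.0, gamma="scale"), seed=9)
        a, _ = cross_validate(X, y, ids, **kwargs)
        b, _ = cross_validate(X, y, ids, **kwargs)
        assert a == b


@pytest.fixture(scope="module")
def tiny_model():
    import pandas as pd

    from mirhairpin import FEATURE_NAMES, generate_shuffled_negatives

    pos = generate_synthetic_hairpins(15, seed=23)
    neg = generate_shuffled_negatives(pos, seed=24)
    featurizer = HairpinFeaturizer(shuffles=10, random_state=2)
    X = featurizer.fit(pos + neg).transform(pos + neg)
    y = np.r_[np.ones(15, int), np.zeros(15, int)]
    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES),
                         index=[s.id for s in pos + neg])
    model = train(frame, y, featurizer=featurizer,
                  estimator=HairpinClassifier(C=8.0, gamma="scale"))
    return model, pos, neg


class TestSequencePipeline:
    def test_training_records_repredicted_consistently(self, tiny_model):
        model, pos, neg = tiny_model
        table = predict_sequences(model, pos + neg)
        assert len(table) == 30
        assert set(table["label"]) <= {"positive", "negative"}

    def test_empty_input_gives_empty_output(self, tiny_model):
        model, _, _ = tiny_model
        assert len(predict_sequences(model, [])) == 0

    def test_batch_equals_record_by_record(self, tiny_model):
        model, pos, _ = tiny_model
        batch = predict_sequences(model, pos[:4])
        singles = [predict_sequences(model, [s]) for s in pos[:4]]
        for k, single in enumerate(singles):
            assert single["label"].iloc[0] == batch["label"].iloc[k]
            assert single["score"].iloc[0] == pytest.approx(batch["score"].iloc[k])

    def test_short_records_skipped_with_warning(self, tiny_model, caplog):
        from mirhairpin import RnaSequence

        model, pos, _ = tiny_model
        out = predict_sequences(model, [RnaSequence("tiny", "AC"), pos[0]])
        assert list(out.index) == [pos[0].id]

    def test_archive_roundtrip(self, tiny_model, tmp_path):
        model, pos, _ = tiny_model
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.manifest()["algorithm"] == "svm_rbf"
        a = predict_sequences(model, pos[:3])
        b = predict_sequences(loaded, pos[:3])
        assert (a["label"] == b["label"]).all()
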