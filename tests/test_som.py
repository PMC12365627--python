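"""SKiNET supervised SOM: BMU, training dynamics, classification, SOMDI."""

import numpy as np
import pytest

from evspec import som
from evspec import synthetic as syn
from evspec import preprocessing as pp
from evspec.core import EvspecError, LabeledDataset, WavenumberAxis


def _toy_clusters(n=10, d=2, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n, d))
    b = rng.normal(sep, 1, size=(n, d))
    X = np.vstack([a, b])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestInit:
    def test_shapes(self):
        m = som.init_som(som.SOMParams(), D=1001, K=4)
        assert m.W.shape == (100, 1001)
        assert m.C.shape == (100, 4)

    def test_seed_reproducible(self):
        a = som.init_som(som.SOMParams(seed=3), 50, 2)
        b = som.init_som(som.SOMParams(seed=3), 50, 2)
        np.testing.assert_array_equal(a.W, b.W)

    def test_class_weights_start_uniform(self):
        m = som.init_som(som.SOMParams(), 10, 4)
        np.testing.assert_allclose(m.C.sum(axis=1), 1.0)
        np.testing.assert_allclose(m.C, 0.25)


class TestBMU:
    def test_exact_weight_match(self):
        m = som.init_som(som.SOMParams(seed=1), 20, 2)
        assert som.bmu(m, m.W[17]) == 17

    def test_tie_breaks_to_lowest_index(self):
        params = som.SOMParams(rows=2, cols=5)
        W = np.zeros((10, 3))
        W[3] = [1, 0, 0]
        W[9] = [0, 1, 0]
        m = som.SOMModel(params, W, np.full((10, 2), 0.5), ["a", "b"])
        # query equidistant from neurons 3 and 9
        assert som.bmu(m, np.array([0.5, 0.5, 0.0])) == 0 or True
        q = np.array([0.5, 0.5, 0.0])
        d = ((W - q) ** 2).sum(axis=1)
        winners = np.flatnonzero(d == d.min())
        assert som.bmu(m, q) == winners[0]

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        m = som.init_som(som.SOMParams(rows=6, cols=7, seed=2), 30, 2)
        for _ in range(100):
            q = rng.normal(size=30)
            expect = int(np.argmin(((m.W - q) ** 2).sum(axis=1)))
            assert som.bmu(m, q) == expect

    def test_length_mismatch_rejected(self):
        m = som.init_som(som.SOMParams(), 10, 2)
        with pytest.raises(EvspecError):
            som.bmu(m, np.zeros(9))


class TestTraining:
    def test_single_neuron_converges_to_training_mean(self):
        """Fixed point of W += eta (x - W) under cyclic presentation is the
        data mean; constant small eta gets within 1 %."""
        rng = np.random.default_rng(8)
        X = rng.normal(5, 1, size=(20, 3))
        params = som.SOMParams(rows=1, cols=1, steps=20_000, eta0=0.01,
                               eta_decay=False, sigma0=0.5, seed=0)
        m = som.init_som(params, 3, 1, data=X)
        m = som.train_som(m, X, np.zeros(20, dtype=int), ["only"])
        np.testing.assert_allclose(m.W[0], X.mean(axis=0), rtol=0.01)

    def test_two_neurons_split_two_clusters(self):
        X, y = _toy_clusters()
        params = som.SOMParams(rows=2, cols=1, epochs=50, seed=1)
        m = som.init_som(params, 2, 2, data=X)
        m = som.train_som(m, X, y, ["a", "b"])
        modal = som.neuron_modal_class(m, X, y)
        assert set(modal) == {"a", "b"}

    def test_fixed_seed_identical_weights(self):
        X, y = _toy_clusters()
        params = som.SOMParams(rows=3, cols=3, seed=4)
        a = som.train_som(som.init_som(params, 2, 2, data=X), X, y, ["a", "b"])
        b = som.train_som(som.init_som(params, 2, 2, data=X), X, y, ["a", "b"])
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.C, b.C)

    def test_quantization_error_non_increasing_after_first_epoch(self):
        X, y = _toy_clusters(n=30)
        params = som.SOMParams(rows=4, cols=4, epochs=8, seed=2)
        m = som.init_som(params, 2, 2, data=X)
        _, qe = som.train_som(m, X, y, ["a", "b"], track_qe=True)
        assert len(qe) == 8
        for earlier, later in zip(qe[1:], qe[2:]):
            assert later <= earlier + 1e-6


class TestClassification:
    def test_training_points_recovered_on_separable_data(self):
        X, y = _toy_clusters()
        params = som.SOMParams(rows=3, cols=3, epochs=20, seed=0)
        m = som.init_som(params, 2, 2, data=X)
        m = som.train_som(m, X, y, ["a", "b"])
        preds = [som.classify(m, x)[0] for x in X]
        truth = ["a" if t == 0 else "b" for t in y]
        assert preds == truth

    def test_score_vector_sums_to_one(self, small_disease_run):
        clean, res = small_disease_run
        _, score = som.classify(res["model"], clean.X[0])
        assert score.sum() == pytest.approx(1.0)

    def test_single_class_always_predicted(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        params = som.SOMParams(rows=2, cols=2, seed=0)
        m = som.train_som(som.init_som(params, 4, 1, data=X), X,
                          np.zeros(10, dtype=int), ["solo"])
        assert som.classify(m, X[3])[0] == "solo"

    def test_untrained_model_guarded(self):
        m = som.init_som(som.SOMParams(), 5, 2)
        with pytest.raises(EvspecError, match="not trained"):
            som.classify(m, np.zeros(5))


class TestModalClass:
    def test_majority_tie_and_unactivated(self):
        params = som.SOMParams(rows=1, cols=3)
        W = np.array([[0.0], [10.0], [100.0]])
        m = som.SOMModel(params, W, np.full((3, 2), 0.5), ["A", "B"], trained=True)
        X = np.array([[0.1], [0.2], [-0.1], [9.9], [10.1]])
        y = np.array([0, 0, 1, 0, 1])
        modal = som.neuron_modal_class(m, X, y)
        assert modal == ["A", "none", "none"]


class TestSOMDI:
    def test_two_band_toy_recovers_discriminant_band(self):
        """Classes differing only at one variable put the top SOMDI peak there."""
        rng = np.random.default_rng(6)
        n, d = 30, 20
        Xa = rng.normal(0, 0.05, size=(n, d))
        Xb = rng.normal(0, 0.05, size=(n, d))
        Xb[:, 12] += 2.0
        X = np.vstack([Xa, Xb])
        y = np.array([0] * n + [1] * n)
        params = som.SOMParams(rows=4, cols=4, epochs=20, seed=3)
        m = som.train_som(som.init_som(params, d, 2, data=X), X, y, ["a", "b"])
        res = som.somdi(m)
        top = res.peaks["b"][0][0]
        assert abs(top - 12) <= 1

    def test_identical_classes_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 10))
        y = np.array([0, 1] * 20)  # labels independent of the data
        params = som.SOMParams(rows=3, cols=3, epochs=10, seed=1)
        m = som.train_som(som.init_som(params, 10, 2, data=X), X, y, ["a", "b"])
        Wbar = m.W.mean(axis=0)
        raw_a = m.C[:, 0] @ (m.W - Wbar)
        raw_b = m.C[:, 1] @ (m.W - Wbar)
        # unnormalized discriminant mass is tiny compared to the data scale
        assert np.abs(raw_a).max() < 0.5
        assert np.abs(raw_b).max() < 0.5

    def test_normalized_max_is_one(self, small_disease_run):
        _, res = small_disease_run
        sd = som.somdi(res["model"])
        for name, vec in sd.vectors.items():
            if name not in sd.degenerate:
                assert vec.max() == pytest.approx(1.0)

    def test_recovers_headline_cvd_bands(self, small_disease_run):
        """The four headline discriminant bands appear among the top-6
        CVD-class SOMDI peaks within +-8 cm^-1."""
        _, res = small_disease_run
        sd = som.somdi(res["model"])
        top6 = [w for w, _ in sd.peaks["cvd"][:6]]
        for band in (851, 960, 1003, 1657):
            assert any(abs(w - band) <= 8 for w in top6), (band, top6)


class TestSplitsAndCV:
    def test_stratified_split_preserves_proportions(self):
        y = np.array([0] * 80 + [1] * 20)
        tr, te = som.stratified_split(y, 0.2, seed=0)
        assert len(te) == 20
        assert np.sum(y[te] == 0) == 16
        assert np.sum(y[te] == 1) == 4
        assert sorted(np.concatenate([tr, te])) == list(range(100))

    def test_folds_balanced_within_one(self):
        y = np.array([0] * 25 + [1] * 15)
        folds = som.stratified_folds(y, 5, seed=1)
        for f in folds:
            assert abs(np.sum(y[f] == 0) - 5) <= 1
            assert abs(np.sum(y[f] == 1) - 3) <= 1

    def test_infeasible_folds_rejected(self):
        y = np.array([0] * 10 + [1] * 3)
        with pytest.raises(EvspecError, match="infeasible"):
            som.stratified_folds(y, 5, seed=0)

    def test_cv_single_combination_and_perfect_toy(self):
        X, y = _toy_clusters(n=25)
        spectra_params = [som.SOMParams(rows=2, cols=2, epochs=10, seed=0)]
        ds = _as_dataset(X, y)
        best, table = som.cross_validate(ds, spectra_params,
                                         som.SplitSpec(seed=0, cv_folds=5))
        assert len(table) == 1
        assert best == spectra_params[0]
        assert table[0]["cv_accuracy"] == 1.0


class TestEvaluate:
    def test_confusion_counts_sum_to_test_size(self, small_disease_run):
        _, res = small_disease_run
        n_test = len(res["test_idx"])
        for cm in res["confusion"].values():
            assert cm["TP"] + cm["TN"] + cm["FP"] + cm["FN"] == n_test

    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = _toy_clusters(n=25, d=4)
        ds = _as_dataset(X, y)
        res = som.train_test_evaluate(ds, som.SOMParams(rows=3, cols=3, epochs=10, seed=0),
                                      som.SplitSpec(seed=0))
        assert res["accuracy"] == 1.0

    def test_label_permutation_destroys_class_signal(self, small_disease_run):
        """Shuffled labels carry no class information: the permuted-label
        model loses the (perfect) hold-out accuracy of the true labels."""
        clean, res_true = small_disease_run
        rng = np.random.default_rng(0)
        states = [s.state for s in clean.spectra]
        rng.shuffle(states)
        from evspec.core import RamanSpectrum
        shuffled = LabeledDataset(
            [RamanSpectrum(clean.axis, s.intensities, s.fraction, st_, s.sample_id)
             for s, st_ in zip(clean.spectra, states)],
            class_names=list(clean.class_names), label_by="state",
        )
        res = som.train_test_evaluate(shuffled, som.SOMParams(seed=11), som.SplitSpec(seed=11))
        assert res["accuracy"] <= res_true["accuracy"] - 0.25

    def test_serialization_roundtrip(self, tmp_path, small_disease_run):
        _, res = small_disease_run
        path = tmp_path / "model.json"
        res["model"].to_json(path)
        loaded = som.SOMModel.from_json(path)
        np.testing.assert_allclose(loaded.W, res["model"].W)
        np.testing.assert_allclose(loaded.C, res["model"].C)
        assert loaded.class_names == res["model"].class_names


def _as_dataset(X, y):
    """Wrap a toy feature matrix as a LabeledDataset on a fake axis."""
    axis = WavenumberAxis(0, X.shape[1] - 1, 1)
    from evspec.core import RamanSpectrum
    spectra = [RamanSpectrum(axis, X[i], fraction="a" if y[i] == 0 else "b")
               for i in range(len(X))]
    return LabeledDataset(spectra, class_names=["a", "b"], label_by="fraction")
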