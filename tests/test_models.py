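"""Hybrid network estimators, baseline grid, consensus regressor."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LinearRegression, LogisticRegression

from mixcarc.errors import ManifestError
from mixcarc.models import (
    HybridNetClassifier,
    HybridNetRegressor,
    build_baseline,
    consensus_predict,
    pack_hybrid_input,
)

SMALL = dict(embedding_dim=16, conv_filters=16, conv_kernel=3,
             hidden_layer_sizes=(32, 16), merge_units=16, batch_size=32)


def cluster_data(n=500, p=10, seed=0, separation=3.0):
    """Two well-separated descriptor clusters; a linear probe reaches 1.0."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, p))
    X[:, :3] += separation * (2 * y[:, None] - 1)
    return X, y


def token_signal_data(n=400, L=30, seed=0):
    """Label carried only by a 3-token motif in the sequence; descriptors are noise."""
    rng = np.random.default_rng(seed)
    tokens = rng.integers(1, 95, size=(n, L))
    y = rng.integers(0, 2, size=n)
    motif = np.array([39, 40, 41])
    for i in range(n):
        pos = rng.integers(0, L - 3)
        if y[i] == 1:
            tokens[i, pos:pos + 3] = motif
        else:  # scrub accidental motifs
            row = tokens[i]
            for j in range(L - 2):
                if (row[j:j + 3] == motif).all():
                    row[j] = 50
    desc = rng.normal(size=(n, 5))
    return tokens, desc, y


class TestHybridClassifierContracts:
    def test_binary_probabilities_in_unit_interval(self):
        X, y = cluster_data(n=200)
        clf = HybridNetClassifier(smiles_length=0, epochs=5, random_state=0, **SMALL)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (200, 2)
        assert (proba >= 0).all() and (proba <= 1).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_multiclass_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, size=300)
        X = rng.normal(size=(300, 8))
        X[:, :3] += 3.0 * np.eye(3)[y]
        clf = HybridNetClassifier(smiles_length=0, epochs=15, random_state=0, **SMALL)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (300, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(clf.predict(X)) <= {0, 1, 2}
        assert (clf.predict(X) == y).mean() > 0.9

    def test_embedding_contract_is_k_by_l_by_dim(self):
        tokens, desc, y = token_signal_data(n=40)
        clf = HybridNetClassifier(smiles_length=30, epochs=1, random_state=0, **SMALL)
        clf.fit(pack_hybrid_input(tokens, desc), y)
        E = clf.net_.params["emb"][tokens]
        assert E.shape == (40, 30, 16)

    def test_seeded_determinism(self):
        X, y = cluster_data(n=150)
        a = HybridNetClassifier(smiles_length=0, epochs=5, random_state=7, **SMALL).fit(X, y)
        b = HybridNetClassifier(smiles_length=0, epochs=5, random_state=7, **SMALL).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))
        assert a.loss_curve_ == b.loss_curve_

    def test_prediction_is_permutation_equivariant(self):
        X, y = cluster_data(n=120)
        clf = HybridNetClassifier(smiles_length=0, epochs=5, random_state=0, **SMALL).fit(X, y)
        perm = np.random.default_rng(3).permutation(len(X))
        np.testing.assert_allclose(
            clf.predict_proba(X)[perm], clf.predict_proba(X[perm]), atol=1e-12
        )

    def test_manifest_guard_rejects_wrong_width(self):
        X, y = cluster_data(n=80)
        clf = HybridNetClassifier(smiles_length=0, epochs=2, random_state=0, **SMALL).fit(X, y)
        with pytest.raises(ManifestError):
            clf.predict(X[:, :-1])

    def test_token_columns_validated(self):
        tokens, desc, y = token_signal_data(n=30)
        tokens = tokens.astype(float)
        tokens[0, 0] = 99.0
        clf = HybridNetClassifier(smiles_length=30, epochs=1, random_state=0, **SMALL)
        with pytest.raises(ValueError, match="token"):
            clf.fit(pack_hybrid_input(tokens, desc), y)


class TestLearnerSanity:
    def test_separable_clusters_learned(self):
        """Training accuracy >= 0.95 where a logistic probe reaches 1.0."""
        X, y = cluster_data(n=500)
        assert LogisticRegression(max_iter=1000).fit(X, y).score(X, y) == 1.0  # oracle
        clf = HybridNetClassifier(smiles_length=0, epochs=25, random_state=0, **SMALL)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_linear_regression_signal_recovered(self):
        """Held-out R^2 >= 0.95 on targets linear in 5 descriptors (lstsq gets 1.0)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 10))
        w = np.array([2.0, -1.0, 0.5, 1.5, -2.0])
        y = X[:, :5] @ w
        oracle = LinearRegression().fit(X[:800], y[:800])
        assert oracle.score(X[800:], y[800:]) > 0.999
        reg = HybridNetRegressor(smiles_length=0, epochs=80, dropout=0.0,
                                 random_state=0, **SMALL)
        reg.fit(X[:800], y[:800])
        ss_res = np.sum((reg.predict(X[800:]) - y[800:]) ** 2)
        ss_tot = np.sum((y[800:] - y[800:].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.95


class TestBranchAblation:
    def test_descriptor_signal_needs_no_cnn(self):
        X, y = cluster_data(n=400)
        rng = np.random.default_rng(5)
        tokens = rng.integers(1, 95, size=(400, 20))  # pure noise branch
        full = HybridNetClassifier(smiles_length=20, epochs=20, random_state=0, **SMALL)
        full.fit(pack_hybrid_input(tokens, X), y)
        ffnn = HybridNetClassifier(smiles_length=0, epochs=20, random_state=0, **SMALL)
        ffnn.fit(X, y)
        acc_full = (full.predict(pack_hybrid_input(tokens, X)) == y).mean()
        acc_ffnn = (ffnn.predict(X) == y).mean()
        assert acc_ffnn >= 0.95
        assert abs(acc_full - acc_ffnn) <= 0.05  # within noise of each other

    def test_token_signal_needs_the_cnn(self):
        tokens, desc, y = token_signal_data(n=400)
        X = pack_hybrid_input(tokens, desc)
        full = HybridNetClassifier(smiles_length=30, epochs=30, random_state=0, **SMALL)
        full.fit(X, y)
        acc_full = (full.predict(X) == y).mean()
        ffnn = HybridNetClassifier(smiles_length=0, epochs=30, random_state=0, **SMALL)
        ffnn.fit(desc, y)
        acc_ffnn = (ffnn.predict(desc) == y).mean()
        assert acc_full >= 0.9  # the CNN branch finds the motif
        assert acc_ffnn <= 0.65  # descriptors alone are chance-level


class TestBaselines:
    @pytest.mark.parametrize("method,task", [
        ("RF", "binary"), ("bagging", "binary"), ("AdaBoost", "binary"),
        ("RF", "multiclass"), ("bagging", "multiclass"), ("AdaBoost", "multiclass"),
        ("RF", "regression"), ("SVR", "regression"), ("GB", "regression"),
        ("KR", "regression"), ("DT", "regression"), ("KN", "regression"),
        ("NN", "regression"),
    ])
    def test_supported_grid(self, method, task):
        est = build_baseline(method, task)
        assert hasattr(est, "fit") and hasattr(est, "predict")

    @pytest.mark.parametrize("method,task", [
        ("SVR", "binary"), ("KN", "multiclass"), ("bagging", "regression"),
        ("HNN", "binary"), ("RF", "clustering"),
    ])
    def test_unsupported_combinations(self, method, task):
        with pytest.raises(ValueError):
            build_baseline(method, task)

    def test_baselines_are_cloneable_and_seeded(self):
        est = build_baseline("RF", "binary", random_state=11)
        assert clone(est).get_params()["random_state"] == 11


class TestConsensus:
    def test_mean_of_seven(self):
        preds = [np.full(3, float(i)) for i in range(1, 8)]
        np.testing.assert_allclose(consensus_predict(preds), [4.0, 4.0, 4.0])

    def test_idempotent_on_identical_inputs(self):
        v = np.array([1.5, -2.0])
        np.testing.assert_array_equal(consensus_predict([v] * 7), v)

    def test_matches_brute_force_loop(self, rng):
        preds = [rng.normal(size=50) for _ in range(7)]
        out = consensus_predict(preds)
        for i in range(50):
            expect = sum(p[i] for p in preds) / 7.0
            assert abs(out[i] - expect) < 1e-12

    def test_wrong_count_or_misaligned(self):
        with pytest.raises(ValueError):
            consensus_predict([np.zeros(3)] * 6)
        bad = [np.zeros(3)] * 6 + [np.zeros(4)]
        with pytest.raises(ValueError):
            consensus_predict(bad)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        from mixcarc.models import load_model, save_model

        X, y = cluster_data(n=100)
        clf = HybridNetClassifier(smiles_length=0, epochs=3, random_state=0, **SMALL).fit(X, y)
        path = tmp_path / "model.joblib"
        save_model(clf, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict_proba(X), clf.predict_proba(X))
        assert loaded.manifest_ == clf.manifest_
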