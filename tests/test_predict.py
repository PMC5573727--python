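"""One-hot encoding, naive Bayes, SVR, folding features, AUC."""

import numpy as np
import pytest

from elmseq import simulate as sim
from elmseq.folding import NussinovProvider, window_scan
from elmseq.predict import (
    auc,
    build_features,
    decode_one_hot,
    one_hot,
    one_hot_matrix,
    predict_nb,
    predict_svr,
    train_nb,
    train_svr,
)
from elmseq.templates import get_template

from conftest import random_seqs


class TestOneHot:
    def test_verbatim_encoding(self):
        assert one_hot("A").tolist() == [1, 0, 0, 0]
        assert one_hot("ACGT").tolist() == [
            1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1
        ]

    def test_round_trip(self, rng):
        for seq in random_seqs(rng, 20, 12):
            assert decode_one_hot(one_hot(seq)) == seq

    def test_block_structure(self, rng):
        X = one_hot_matrix(random_seqs(rng, 30, 9))
        assert X.shape == (30, 36)
        assert np.all(X.reshape(30, 9, 4).sum(axis=2) == 1)
        assert np.all(X.sum(axis=1) == 9)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            one_hot("ACGN")


class TestNaiveBayes:
    def test_separable_feature_gives_perfect_training_auc(self, rng):
        seqs = ["A" + s for s in random_seqs(rng, 100, 5)]
        seqs += ["C" + s for s in random_seqs(rng, 100, 5)]
        labels = np.array(["high"] * 100 + ["low"] * 100)
        X = one_hot_matrix(seqs)
        model = train_nb(X, labels)
        assert auc(labels == "high", predict_nb(model, X)) == 1.0

    def test_null_labels_give_chance_auc(self, rng):
        X = one_hot_matrix(random_seqs(rng, 2_000, 10))
        labels = np.where(rng.random(2_000) < 0.5, "high", "low")
        model = train_nb(X[:1_000], labels[:1_000])
        score = auc(labels[1_000:] == "high", predict_nb(model, X[1_000:]))
        assert score == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self, rng):
        X = one_hot_matrix(random_seqs(rng, 60, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_nb(X, np.array(["high"] * 60))

    def test_posterior_stable_under_training_duplication(self, rng):
        """Duplicating the training set barely moves smoothed posteriors.

        Laplace smoothing keeps the posteriors from being exactly invariant
        at finite n; the perturbation shrinks as counts grow and never flips
        a confident call here.
        """
        seqs = random_seqs(rng, 200, 6)
        labels = np.where(
            [s[0] in "AG" for s in seqs], "high", "low"
        )
        X = one_hot_matrix(seqs)
        m1 = train_nb(X, labels)
        m2 = train_nb(np.vstack([X, X]), np.r_[labels, labels])
        probe = one_hot_matrix(random_seqs(rng, 50, 6))
        p1, p2 = predict_nb(m1, probe), predict_nb(m2, probe)
        assert np.allclose(p1, p2, atol=0.05)
        assert np.array_equal(p1 > 0.5, p2 > 0.5)


class TestSVR:
    def test_recovers_linear_function_within_tube(self, rng):
        X = one_hot_matrix(random_seqs(rng, 400, 8)).astype(float)
        y = 3.0 * X[:, 0]  # depends on one feature only
        model = train_svr(X[:300], y[:300], epsilon=1e-3, c=100.0,
                          kernel="linear")
        pred = predict_svr(model, X[300:])
        assert np.max(np.abs(pred - y[300:])) < 1e-3 + 1e-2

    def test_permuted_targets_destroy_prediction(self, rng):
        """Permuting y leaves only chance-level test correlation.

        The RBF predictor concentrates its variance on the few feature
        directions that correlate with the (permuted) targets by chance, so
        the permutation null for the test correlation is wide (about
        +/- 0.15 at n = 1,000) rather than 1/sqrt(n); the check contrasts
        it against the intact fit instead of asserting a tight zero.
        """
        seqs = random_seqs(rng, 2_000, 10)
        X = one_hot_matrix(seqs).astype(float)
        y = np.array([(s[0] in "AG") * 1.0 for s in seqs]) + rng.normal(
            0, 0.1, 2_000
        )
        y_perm = rng.permutation(y)
        r_perm = np.corrcoef(
            predict_svr(train_svr(X[:1_000], y_perm[:1_000]), X[1_000:]),
            y[1_000:],
        )[0, 1]
        r_real = np.corrcoef(
            predict_svr(train_svr(X[:1_000], y[:1_000]), X[1_000:]),
            y[1_000:],
        )[0, 1]
        assert abs(r_perm) < 0.45  # 3 sigma of the permutation null
        assert r_real - abs(r_perm) > 0.5

    def test_constant_target_rejected(self, rng):
        X = one_hot_matrix(random_seqs(rng, 100, 5)).astype(float)
        with pytest.raises(ValueError, match="constant target"):
            train_svr(X, np.ones(100))

    def test_feature_count_mismatch_rejected(self, rng):
        X = one_hot_matrix(random_seqs(rng, 60, 5)).astype(float)
        model = train_svr(X, rng.normal(size=60))
        with pytest.raises(ValueError, match="feature count"):
            predict_svr(model, X[:, :-4])


class TestBuildFeatures:
    @pytest.fixture(scope="class")
    def utr_data(self):
        rng = np.random.default_rng(55)
        template = get_template("utr_strong")
        variants = random_seqs(rng, 80, 25)
        mrnas = [template.mrna(v) for v in variants]
        return rng, variants, mrnas

    def test_no_positive_window_falls_back_to_one_hot(self, utr_data):
        rng, variants, mrnas = utr_data
        provider = NussinovProvider()
        scan = window_scan(
            mrnas, rng.normal(0, 1, len(mrnas)), (-25, -25), (20, 21),
            provider=provider,
        )
        scan.table["r"] = -np.abs(scan.table["r"])  # force all r <= 0
        with pytest.warns(UserWarning, match="sequence-only"):
            X, windows = build_features(variants, scan, provider, mrnas=mrnas)
        assert windows == [] and X.shape[1] == 100

    def test_feature_count_arithmetic_and_planted_window(self, utr_data):
        rng, variants, mrnas = utr_data
        provider = NussinovProvider()
        dg = provider.fold_many([m[1:56] for m in mrnas])  # window (-25, 30)
        ratios = -dg + rng.normal(0, 0.5, len(mrnas))
        scan = window_scan(
            mrnas, ratios, (-25, -24), (29, 31), provider=provider,
        )
        X, windows = build_features(variants, scan, provider, mrnas=mrnas)
        n_selected = int((scan.table.r.dropna() > 0).sum())
        assert len(windows) == n_selected
        assert X.shape[1] == 4 * 25 + n_selected


class TestAUC:
    def test_perfect_and_tied_scores(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        labels = rng.random(200) < 0.4
        scores = rng.normal(size=200)
        scores[labels] += 0.5
        wins = 0.0
        for sp in scores[labels]:
            for sn in scores[~labels]:
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        oracle = wins / (labels.sum() * (~labels).sum())
        assert auc(labels, scores) == pytest.approx(oracle, abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_complement_identity(self, rng):
        labels = rng.random(100) < 0.5
        scores = rng.normal(size=100)
        assert auc(labels, scores) + auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])


def test_simulated_library_is_learnable():
    """Planted positional effects are recovered by both predictors."""
    cfg = sim.default_promoter_config(n_variants=2_000)
    truth = sim.simulate_library(cfg, seed=91)
    X = one_hot_matrix(truth.index.tolist())
    labels = truth["class_label"].to_numpy()
    y = truth["log_e"].to_numpy()
    model = train_nb(X[:1_500], labels[:1_500])
    score = auc(labels[1_500:] == "high", predict_nb(model, X[1_500:]))
    assert score >= 0.85
    reg = train_svr(X[:1_500].astype(float), y[:1_500])
    r = np.corrcoef(predict_svr(reg, X[1_500:].astype(float)), y[1_500:])[0, 1]
    assert r >= 0.8
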