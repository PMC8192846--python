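"""Pool construction, resampled voting and the two-tier consensus call."""

import numpy as np
import pandas as pd
import pytest

from famrank import ensemble as ens
from famrank.feature_table import standardize


class _StubModel:
    """Deterministic rule: active iff the first feature is positive."""

    def __init__(self, n_features):
        self.n_features_in_ = n_features
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X):
        p = (np.asarray(X)[:, 0] > 0).astype(float)
        return np.c_[1 - p, p]


def stub_train(X_train, y_train, seed):
    return _StubModel(X_train.shape[1])


def toy_matrix(n_pos=8, n_neg=24, n_test=6, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    ids = ([f"P{i}" for i in range(n_pos)] + [f"N{i}" for i in range(n_neg)]
           + [f"T{i}" for i in range(n_test)])
    X = np.vstack([
        rng.normal(sep, 1.0, size=(n_pos, 3)),
        rng.normal(-sep, 1.0, size=(n_neg, 3)),
        rng.normal(sep, 1.0, size=(n_test, 3)),
    ])
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return pd.DataFrame(X, index=ids), ids[:n_pos], ids[n_pos:n_pos + n_neg], \
        ids[n_pos + n_neg:]


class TestBuildPool:
    def test_reference_composition(self):
        pool = ens.build_pool([f"a{i}" for i in range(41)],
                              [f"n{i}" for i in range(140)], neg_ratio=3, seed=0)
        assert len(pool.positive_ids) == 41
        assert len(pool.negative_ids) == 123

    def test_ratio_one_keeps_all(self):
        pool = ens.build_pool(list("abcdefghij"),
                              [f"n{i}" for i in range(10)], neg_ratio=1, seed=1)
        assert len(pool.negative_ids) == 10

    def test_too_few_negatives_reports_feasible_ratio(self):
        with pytest.raises(ens.EnsembleError, match="max feasible ratio is 2"):
            ens.build_pool([f"a{i}" for i in range(41)],
                           [f"n{i}" for i in range(100)], neg_ratio=3, seed=0)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ens.EnsembleError):
            ens.LabeledPool(("a", "b"), ("b", "c"))


class TestSplitPool:
    def test_reference_109_55(self):
        pool = ens.build_pool([f"a{i}" for i in range(41)],
                              [f"n{i}" for i in range(140)], seed=0)
        train, val = ens.split_pool(pool, seed=3)
        assert len(train) == 109
        assert len(val) == 55

    def test_degenerate_fraction_rejected(self):
        pool = ens.LabeledPool(("a", "b"), ("c", "d"))
        with pytest.raises(ens.EnsembleError):
            ens.split_pool(pool, train_fraction=1.0)

    def test_stratification_within_one_gene_of_pool_ratio(self):
        pool = ens.build_pool([f"a{i}" for i in range(41)],
                              [f"n{i}" for i in range(140)], seed=0)
        labels = pool.labels()
        pool_frac = labels.mean()
        for seed in range(100):
            train, _ = ens.split_pool(pool, seed=seed)
            n_pos = int(labels.loc[train].sum())
            expected = pool_frac * len(train)
            assert abs(n_pos - expected) <= 1

    def test_split_is_a_partition(self):
        pool = ens.build_pool(list("abcde"), [f"n{i}" for i in range(15)], seed=2)
        train, val = ens.split_pool(pool, seed=5)
        assert sorted(train + val) == sorted(pool.ids)


class TestTrainPredict:
    def test_separable_toy_trains_to_perfection(self):
        X, pos, neg, _ = toy_matrix()
        spec = ens.ClassifierSpec()
        Xp = X.loc[pos + neg].to_numpy()
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        model = ens.train_classifier(spec, Xp, y, seed=0)
        assert model is not None
        _, y_hat = ens.predict(model, Xp)
        assert (y_hat == y).all()

    def test_same_seed_identical_predictions(self):
        X, pos, neg, test = toy_matrix()
        spec = ens.ClassifierSpec()
        Xp = X.loc[pos + neg].to_numpy()
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        m1 = ens.train_classifier(spec, Xp, y, seed=7)
        m2 = ens.train_classifier(spec, Xp, y, seed=7)
        s1, _ = ens.predict(m1, X.loc[test].to_numpy())
        s2, _ = ens.predict(m2, X.loc[test].to_numpy())
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(
            np.concatenate([c.ravel() for c in m1.coefs_]),
            np.concatenate([c.ravel() for c in m2.coefs_]))

    def test_shuffled_labels_give_chance_validation(self):
        """With no signal the validation accuracy hovers at 0.5."""
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(40)]
        X = pd.DataFrame(rng.normal(size=(40, 4)), index=ids)
        pool = ens.LabeledPool(tuple(ids[:20]), tuple(ids[20:]))
        res = ens.run_round(X, pool, [], ens.ClassifierSpec(), n_resamples=50,
                            vote_threshold=48, round_seed=1)
        mean_acc = res.val_stats["accuracy"].mean()
        assert abs(mean_acc - 0.5) <= 0.1

    def test_threshold_boundary_inclusive(self):
        X, pos, neg, test = toy_matrix()
        spec = ens.ClassifierSpec()
        Xp = X.loc[pos + neg].to_numpy()
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        model = ens.train_classifier(spec, Xp, y, seed=0)

        class Half:
            n_features_in_ = 3
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        _, y_hat = ens.predict(Half(), X.loc[test].to_numpy())
        assert (y_hat == 1).all()  # score exactly 0.5 -> active

    def test_schema_mismatch_rejected(self):
        X, pos, neg, _ = toy_matrix()
        model = _StubModel(3)
        with pytest.raises(ens.EnsembleError, match="schema"):
            ens.predict(model, np.zeros((2, 5)))

    def test_single_class_training_rejected(self):
        with pytest.raises(ens.EnsembleError):
            ens.train_classifier(ens.ClassifierSpec(), np.zeros((4, 2)),
                                 np.zeros(4), seed=0)

    @pytest.mark.parametrize("kind", ["rf", "svm"])
    def test_alternative_classifiers_fit_and_predict(self, kind):
        X, pos, neg, test = toy_matrix()
        spec = ens.ClassifierSpec(kind=kind)
        Xp = X.loc[pos + neg].to_numpy()
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        model = ens.train_classifier(spec, Xp, y, seed=0)
        scores, y_hat = ens.predict(model, X.loc[test].to_numpy())
        assert ((scores >= 0) & (scores <= 1)).all()
        assert y_hat.mean() > 0.5  # test points sit on the positive side


class TestRunRound:
    def test_unanimous_votes_called(self):
        X, pos, neg, test = toy_matrix()
        pool = ens.LabeledPool(tuple(pos), tuple(neg))
        res = ens.run_round(X, pool, test, ens.ClassifierSpec(), n_resamples=10,
                            vote_threshold=10, round_seed=0, train_fn=stub_train)
        votes = res.votes
        assert (votes["n_active_votes"] + votes["n_inactive_votes"]
                + votes["n_abstain"] == 10).all()
        # stub rule: active iff first standardized feature positive
        expected = np.where(X.loc[test].iloc[:, 0] > 0, "active", "inactive")
        assert (res.round_call.to_numpy() == expected).all()

    def test_949_of_1000_is_no_call(self):
        calls = pd.DataFrame({"n_active_votes": [949, 950],
                              "n_inactive_votes": [51, 50]})
        call = np.where(calls["n_active_votes"] >= 950, "active", "none")
        # boundary documented as inclusive >= 950; exercised through run_round
        X, pos, neg, test = toy_matrix(n_test=1)
        pool = ens.LabeledPool(tuple(pos), tuple(neg))

        def almost_train(Xt, yt, seed):
            # votes active in all but one resample via a seed-dependent flip
            class M:
                n_features_in_ = Xt.shape[1]
                classes_ = np.array([0, 1])

                def predict_proba(self, Xq):
                    p = np.ones(len(Xq)) * (0.0 if seed % 20 == 0 else 1.0)
                    return np.c_[1 - p, p]
            return M()

        res = ens.run_round(X, pool, test, ens.ClassifierSpec(),
                            n_resamples=20, vote_threshold=20, round_seed=0,
                            train_fn=almost_train)
        assert (res.votes["n_active_votes"] < 20).all() or \
            (res.round_call == "active").all()
        under = res.votes["n_active_votes"] < 20
        assert (res.round_call[under.to_numpy()] == "none").all()

    def test_overlapping_test_ids_rejected(self):
        X, pos, neg, _ = toy_matrix()
        pool = ens.LabeledPool(tuple(pos), tuple(neg))
        with pytest.raises(ens.EnsembleError):
            ens.run_round(X, pool, [pos[0]], ens.ClassifierSpec(),
                          n_resamples=5, vote_threshold=5, round_seed=0)

    def test_threshold_above_resamples_rejected(self):
        X, pos, neg, test = toy_matrix()
        pool = ens.LabeledPool(tuple(pos), tuple(neg))
        with pytest.raises(ens.EnsembleError):
            ens.run_round(X, pool, test, ens.ClassifierSpec(),
                          n_resamples=10, vote_threshold=11, round_seed=0)


def stub_round_calls(per_gene):
    """Build a round-call frame from {gene: list of calls}."""
    return pd.DataFrame(per_gene).T.rename(columns=lambda i: f"round_{i}")


class TestConsensusAcrossRounds:
    def test_unanimous_active(self):
        rc = stub_round_calls({"g": ["active"] * 10})
        out = ens.consensus_across_rounds(rc, min_rounds=9)
        assert out.loc["g", "final"] == "active"

    def test_eight_of_ten_unclassified(self):
        rc = stub_round_calls({"g": ["active"] * 8 + ["none"] * 2})
        out = ens.consensus_across_rounds(rc, min_rounds=9)
        assert out.loc["g", "final"] == "unclassified"

    def test_nine_active_one_inactive_is_active(self):
        rc = stub_round_calls({"g": ["active"] * 9 + ["inactive"]})
        out = ens.consensus_across_rounds(rc, min_rounds=9)
        assert out.loc["g", "final"] == "active"

    def test_missing_gene_in_a_round_rejected(self):
        rc = stub_round_calls({"g": ["active"] * 10})
        rc.iloc[0, 3] = np.nan
        with pytest.raises(ens.EnsembleError):
            ens.consensus_across_rounds(rc, min_rounds=9)

    def test_monotone_in_min_rounds(self, rng):
        genes = {f"g{i}": list(rng.choice(["active", "inactive", "none"], 10))
                 for i in range(50)}
        rc = stub_round_calls(genes)
        called_sizes = []
        for mr in range(6, 11):
            out = ens.consensus_across_rounds(rc, min_rounds=mr)
            called_sizes.append((out["final"] != "unclassified").sum())
        assert all(b <= a for a, b in zip(called_sizes, called_sizes[1:]))

    def test_active_inactive_disjoint(self, rng):
        genes = {f"g{i}": list(rng.choice(["active", "inactive", "none"], 10))
                 for i in range(200)}
        out = ens.consensus_across_rounds(stub_round_calls(genes), min_rounds=6)
        act = set(out.index[out["final"] == "active"])
        inact = set(out.index[out["final"] == "inactive"])
        assert not act & inact


class TestRunEnsembleMonotonicity:
    def test_vote_threshold_monotone_on_stub(self):
        X, pos, neg, test = toy_matrix(n_test=10, sep=0.3, seed=9)
        pool = ens.LabeledPool(tuple(pos), tuple(neg))
        sizes = []
        for thr in (5, 7, 9, 10):
            res = ens.run_round(X, pool, test, ens.ClassifierSpec(),
                                n_resamples=10, vote_threshold=thr,
                                round_seed=4, train_fn=stub_train)
            sizes.append(int((res.round_call != "none").sum()))
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_full_determinism(self):
        X, pos, neg, test = toy_matrix()
        pool = ens.LabeledPool(tuple(pos), tuple(neg))
        outs = []
        for _ in range(2):
            res = ens.run_ensemble(X, pool, test, n_rounds=2, n_resamples=8,
                                   vote_threshold=7, min_rounds=2,
                                   master_seed=21)
            outs.append(res.calls.to_csv())
        assert outs[0] == outs[1]
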