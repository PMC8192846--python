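"""Two-tier resampling-consensus supervised classification.

The labeled pool treats substrate-characterized genes (Group I) as active
(label 1) and never-studied genes (Group IV) as inactive (label 0), with
negatives downsampled to a 1:3 positive:negative ratio.  Each *round*
resamples the pool many times; every resample draws a fresh stratified 2:1
train/validation split, trains a base classifier and votes on every test
gene.  A gene gets a *round call* only if one class collects at least
``vote_threshold`` of the ``n_resamples`` votes (the reference setting is
950 of 1,000), and a *final call* only if at least ``min_rounds`` of
``n_rounds`` rounds agree (reference: 9 of 10).  With ``min_rounds >
n_rounds/2`` the final active and inactive sets are provably disjoint.

All thresholds are inclusive (≥).  Every source of randomness derives from a
master seed through a documented counter scheme
(``SeedSequence(master, spawn_key=(round, resample))``-style spawning), so
any single resample is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    """Base-classifier settings.

    The multilayer perceptron is the reference architecture: two hidden
    layers of 10 and 2 logistic units trained full-batch to convergence.
    Random forest (mtry = 4) and radial-kernel C-classification SVM are
    contract-level alternatives delegated to scikit-learn.
    """

    kind: str = "mlp"                       # {mlp, rf, svm}
    mlp_hidden: tuple[int, ...] = (10, 2)
    mlp_activation: str = "logistic"
    mlp_max_iter: int = 2000
    rf_n_estimators: int = 500
    rf_mtry: int = 4
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.kind not in {"mlp", "rf", "svm"}:
            raise EnsembleError(f"unknown classifier kind {self.kind!r}")
        if any(h <= 0 for h in self.mlp_hidden):
            raise EnsembleError("hidden layer sizes must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise EnsembleError("decision threshold must be in (0, 1)")


@dataclass(frozen=True)
class LabeledPool:
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]

    def __post_init__(self):
        if set(self.positive_ids) & set(self.negative_ids):
            raise EnsembleError("positive and negative ids overlap")

    @property
    def ids(self) -> list[str]:
        return list(self.positive_ids) + list(self.negative_ids)

    def labels(self) -> pd.Series:
        return pd.Series(
            [1] * len(self.positive_ids) + [0] * len(self.negative_ids),
            index=self.ids, name="label")


def build_pool(active_ids, inactive_candidate_ids, neg_ratio: int = 3,
               seed: int = 0) -> LabeledPool:
    """Downsample negatives to ``neg_ratio`` × positives, uniformly, seeded."""
    pos = list(active_ids)
    neg = list(inactive_candidate_ids)
    needed = neg_ratio * len(pos)
    if len(neg) < needed:
        feasible = len(neg) // len(pos) if pos else 0
        raise EnsembleError(
            f"need {needed} negatives for ratio {neg_ratio} but only "
            f"{len(neg)} available; max feasible ratio is {feasible}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg), size=needed, replace=False)
    return LabeledPool(tuple(pos), tuple(neg[i] for i in np.sort(chosen)))


def split_pool(pool: LabeledPool, train_fraction: float = 2.0 / 3.0,
               seed: int = 0, stratified: bool = True
               ) -> tuple[list[str], list[str]]:
    """Stratified train/validation split by the global-count rule.

    The train size is ``floor(train_fraction * n)`` overall (164 genes at
    2/3 give 109 train / 55 validate); per-class sizes follow floor
    allocation with the remainder going to classes by largest fractional
    part.  Errors if either side would miss a class.
    """
    labels = pool.labels()
    n = len(labels)
    if n == 0:
        raise EnsembleError("empty pool")
    n_train = int(np.floor(train_fraction * n))
    if n_train <= 0 or n_train >= n:
        raise EnsembleError(
            f"train_fraction={train_fraction} leaves an empty side "
            f"({n_train} of {n} in training)")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(labels.index.to_numpy())
        train, val = list(perm[:n_train]), list(perm[n_train:])
    else:
        classes = [np.asarray(pool.positive_ids), np.asarray(pool.negative_ids)]
        exact = [train_fraction * len(c) for c in classes]
        base = [int(np.floor(e)) for e in exact]
        rem = n_train - sum(base)
        order = np.argsort([-(e - b) for e, b in zip(exact, base)])
        for i in range(rem):
            base[order[i % len(base)]] += 1
        train, val = [], []
        for c, b in zip(classes, base):
            perm = rng.permutation(c)
            train.extend(perm[:b])
            val.extend(perm[b:])
    y_train = labels.loc[train]
    y_val = labels.loc[val]
    if y_train.nunique() < 2 or y_val.nunique() < 2:
        raise EnsembleError("a class is absent from train or validation split")
    return train, val


def train_classifier(spec: ClassifierSpec, X_train, y_train, seed: int = 0,
                     max_retries: int = 3):
    """Fit one base classifier; returns the model or None (abstention).

    The MLP trains with seeded initialization (full-batch L-BFGS); if it
    fails to converge it retries up to ``max_retries`` fresh seeded inits
    and finally abstains (None) so its votes count in neither tally.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise EnsembleError("training data must contain both classes")
    if spec.kind == "rf":
        model = RandomForestClassifier(
            n_estimators=spec.rf_n_estimators, max_features=spec.rf_mtry,
            random_state=seed % (2 ** 31))
        return model.fit(X_train, y_train)
    if spec.kind == "svm":
        # C-classification SVM; Platt-style calibration supplies the
        # probability scores the voting rule consumes
        svc = SVC(kernel=spec.svm_kernel, C=spec.svm_c,
                  random_state=seed % (2 ** 31))
        model = CalibratedClassifierCV(svc, ensemble=False, cv=3)
        return model.fit(X_train, y_train)
    ss = np.random.SeedSequence(seed)
    for _ in range(max_retries + 1):
        init_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        model = MLPClassifier(
            hidden_layer_sizes=spec.mlp_hidden, activation=spec.mlp_activation,
            solver="lbfgs", max_iter=spec.mlp_max_iter, random_state=init_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X_train, y_train)
        if model.n_iter_ < spec.mlp_max_iter:
            return model
    return None


def predict(model, X, decision_threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene active score in [0, 1] and label by the inclusive threshold.

    A score exactly at the threshold is called active.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise EnsembleError(
            f"feature schema mismatch: model expects {model.n_features_in_} "
            f"features, got {X.shape[1] if X.ndim == 2 else X.ndim}")
    proba = model.predict_proba(X)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    scores = proba[:, pos_col]
    return scores, (scores >= decision_threshold).astype(int)


@dataclass
class RoundResult:
    """Vote tallies and validation statistics for one round."""

    round_index: int
    votes: pd.DataFrame            # per test gene: n_active_votes, n_inactive_votes, n_abstain
    round_call: pd.Series          # {active, inactive, none}
    val_stats: pd.DataFrame        # per resample: tp, fn, tn, fp, accuracy
    n_resamples: int
    n_abstained_fits: int = 0


def run_round(X: pd.DataFrame, pool: LabeledPool, test_ids, spec: ClassifierSpec,
              n_resamples: int = 1000, vote_threshold: int = 950,
              round_seed: int = 0, round_index: int = 0,
              train_fraction: float = 2.0 / 3.0, stratified: bool = True,
              train_fn=None) -> RoundResult:
    """One round: ``n_resamples`` fresh splits, fits, and test-gene votes.

    ``X`` is the standardized feature matrix over pool ∪ test genes.
    ``train_fn(X_train, y_train, seed) -> model|None`` may replace the
    built-in classifiers (used for deterministic stubs in testing).
    """
    test_ids = list(test_ids)
    if set(test_ids) & set(pool.ids):
        raise EnsembleError("test ids overlap the labeled pool")
    if vote_threshold > n_resamples:
        raise EnsembleError("vote_threshold exceeds n_resamples")
    labels = pool.labels()
    X_test = X.loc[test_ids].to_numpy(dtype=float)
    active_votes = np.zeros(len(test_ids), dtype=int)
    inactive_votes = np.zeros(len(test_ids), dtype=int)
    abstain = np.zeros(len(test_ids), dtype=int)
    val_rows = []
    n_abstained = 0
    ss = np.random.SeedSequence(round_seed)
    for r in range(n_resamples):
        child = ss.spawn(1)[0]
        split_seed, fit_seed = (int(s % (2 ** 31))
                                for s in child.generate_state(2))
        train, val = split_pool(pool, train_fraction, seed=split_seed,
                                stratified=stratified)
        X_tr = X.loc[train].to_numpy(dtype=float)
        y_tr = labels.loc[train].to_numpy()
        if train_fn is not None:
            model = train_fn(X_tr, y_tr, fit_seed)
        else:
            model = train_classifier(spec, X_tr, y_tr, seed=fit_seed)
        if model is None:
            n_abstained += 1
            abstain += 1
            continue
        X_val = X.loc[val].to_numpy(dtype=float)
        y_val = labels.loc[val].to_numpy()
        _, y_hat = predict(model, X_val, spec.decision_threshold)
        tp = int(((y_val == 1) & (y_hat == 1)).sum())
        fn = int(((y_val == 1) & (y_hat == 0)).sum())
        tn = int(((y_val == 0) & (y_hat == 0)).sum())
        fp = int(((y_val == 0) & (y_hat == 1)).sum())
        val_rows.append((tp, fn, tn, fp, (tp + tn) / len(y_val)))
        if test_ids:
            _, y_test = predict(model, X_test, spec.decision_threshold)
            active_votes += y_test
            inactive_votes += 1 - y_test
    votes = pd.DataFrame(
        {"n_active_votes": active_votes, "n_inactive_votes": inactive_votes,
         "n_abstain": abstain},
        index=pd.Index(test_ids, name="gene_id"))
    call = np.where(active_votes >= vote_threshold, "active",
                    np.where(inactive_votes >= vote_threshold, "inactive",
                             "none"))
    round_call = pd.Series(call, index=votes.index, name=f"round_{round_index}")
    val_stats = pd.DataFrame(val_rows,
                             columns=["tp", "fn", "tn", "fp", "accuracy"])
    return RoundResult(round_index=round_index, votes=votes,
                       round_call=round_call, val_stats=val_stats,
                       n_resamples=n_resamples, n_abstained_fits=n_abstained)


def consensus_across_rounds(round_calls: pd.DataFrame, min_rounds: int = 9
                            ) -> pd.DataFrame:
    """Cross-round consensus: final call needs ≥ ``min_rounds`` agreeing rounds.

    ``round_calls`` has one column per round with values in
    {active, inactive, none}; a missing entry means the gene was absent from
    a round, which is an error.  Returns per gene ``rounds_active``,
    ``rounds_inactive`` and ``final`` in {active, inactive, unclassified}.
    """
    if round_calls.isna().any().any():
        raise EnsembleError("inconsistent gene sets across rounds")
    n_rounds = round_calls.shape[1]
    if min_rounds > n_rounds:
        raise EnsembleError("min_rounds exceeds the number of rounds")
    rounds_active = (round_calls == "active").sum(axis=1)
    rounds_inactive = (round_calls == "inactive").sum(axis=1)
    final = np.where(rounds_active >= min_rounds, "active",
                     np.where(rounds_inactive >= min_rounds, "inactive",
                              "unclassified"))
    if min_rounds > n_rounds / 2:
        assert not ((rounds_active >= min_rounds)
                    & (rounds_inactive >= min_rounds)).any()
    return pd.DataFrame(
        {"rounds_active": rounds_active, "rounds_inactive": rounds_inactive,
         "final": final},
        index=round_calls.index)


@dataclass
class EnsembleResult:
    calls: pd.DataFrame                  # consensus_across_rounds output + vote stats
    rounds: list[RoundResult] = field(default_factory=list)


def run_ensemble(X: pd.DataFrame, pool: LabeledPool, test_ids,
                 spec: ClassifierSpec | None = None, n_rounds: int = 10,
                 n_resamples: int = 1000, vote_threshold: int = 950,
                 min_rounds: int = 9, master_seed: int = 0,
                 train_fraction: float = 2.0 / 3.0, stratified: bool = True,
                 train_fn=None) -> EnsembleResult:
    """Full two-tier procedure: rounds of resampled voting + consensus call."""
    spec = spec or ClassifierSpec()
    ss = np.random.SeedSequence(master_seed)
    rounds = []
    for i in range(n_rounds):
        round_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        rounds.append(run_round(
            X, pool, test_ids, spec, n_resamples=n_resamples,
            vote_threshold=vote_threshold, round_seed=round_seed,
            round_index=i, train_fraction=train_fraction,
            stratified=stratified, train_fn=train_fn))
    round_calls = pd.concat([r.round_call for r in rounds], axis=1)
    calls = consensus_across_rounds(round_calls, min_rounds=min_rounds)
    mean_vote = np.mean(
        [r.votes["n_active_votes"] / np.maximum(
            r.votes["n_active_votes"] + r.votes["n_inactive_votes"], 1)
         for r in rounds], axis=0)
    calls["mean_vote_fraction"] = mean_vote
    return EnsembleResult(calls=calls, rounds=rounds)
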