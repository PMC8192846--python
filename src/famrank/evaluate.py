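"""Performance metrics and biological verification of the consensus calls.

Covers validation-set scoring (accuracy, class-conditional false rates),
the normalized prediction precision used to compare classifiers (validation
accuracy divided by the total number of test-set genes called), enrichment
of internal-control genes among the calls, call-set overlaps, Welch's
t-test, and the balanced expression/evolution comparison of predicted
active vs predicted inactive vs reference-active genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .categorize import fisher_exact, kruskal_dunn_bh


class EvaluationError(ValueError):
    pass


@dataclass
class PredictionMetrics:
    validation_accuracy: float        # mean per-resample accuracy
    false_negative_rate: float        # known-active called inactive (pooled)
    false_positive_rate: float        # known-inactive called active (pooled)
    n_resamples_scored: int


def score_validation(round_results) -> PredictionMetrics:
    """Aggregate validation performance over all resamples of all rounds.

    Accuracy is the mean of per-resample accuracies; the false-negative and
    false-positive rates pool the class-conditional confusion counts across
    resamples (abstained fits contribute nothing and are logged upstream).
    """
    stats = pd.concat([r.val_stats for r in round_results], ignore_index=True)
    if stats.empty:
        raise EvaluationError("no validation resamples to score")
    tp, fn = stats["tp"].sum(), stats["fn"].sum()
    tn, fp = stats["tn"].sum(), stats["fp"].sum()
    fnr = fn / (fn + tp) if fn + tp > 0 else float("nan")
    fpr = fp / (fp + tn) if fp + tn > 0 else float("nan")
    return PredictionMetrics(
        validation_accuracy=float(stats["accuracy"].mean()),
        false_negative_rate=float(fnr),
        false_positive_rate=float(fpr),
        n_resamples_scored=len(stats))


def normalized_precision(accuracy: float, n_called_active: int,
                         n_called_inactive: int) -> float:
    """Validation accuracy ÷ total test-set calls; NaN when nothing is called.

    Penalizes methods that reach their accuracy by calling indiscriminately
    many genes; an undefined value (no calls) is flagged as NaN rather than
    raised.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise EvaluationError(f"accuracy must be in [0, 1], got {accuracy!r}")
    if n_called_active < 0 or n_called_inactive < 0:
        raise EvaluationError("call counts must be non-negative")
    denom = n_called_active + n_called_inactive
    return accuracy / denom if denom > 0 else float("nan")


@dataclass
class EnrichmentResult:
    fraction_in_active: float
    fraction_in_inactive: float
    odds_ratio: float
    p: float


def control_enrichment(control_ids, called_active, called_inactive
                       ) -> EnrichmentResult:
    """Are internal-control genes enriched among the called-active set?

    Fractions are the share of each called set made up of controls; the
    p-value is Fisher's exact test on control status × call.  Empty called
    sets yield NaN fractions (flagged, not raised).
    """
    controls = set(control_ids)
    act = set(called_active)
    inact = set(called_inactive)
    if act & inact:
        raise EvaluationError("called active and inactive sets overlap")
    fa = len(act & controls) / len(act) if act else float("nan")
    fi = len(inact & controls) / len(inact) if inact else float("nan")
    table = [[len(act & controls), len(act - controls)],
             [len(inact & controls), len(inact - controls)]]
    odds, p = fisher_exact(table)
    return EnrichmentResult(fa, fi, odds, p)


@dataclass
class OverlapCounts:
    n_a: int
    n_b: int
    n_common: int
    n_only_a: int
    n_only_b: int


def overlap(set_a, set_b) -> OverlapCounts:
    """Exact set algebra for comparing two call sets (Venn counts)."""
    a, b = set(set_a), set(set_b)
    return OverlapCounts(len(a), len(b), len(a & b), len(a - b), len(b - a))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, p).

    Two samples with zero variance and equal means give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise EvaluationError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


DEFAULT_VERIFY_FEATURES = ("expr_mean", "expr_median", "expr_cv",
                           "ka_ks", "ks", "fbxd_evalue_exp")


def verify_groups(features: pd.DataFrame, called_active, called_inactive,
                  reference_active_ids, seed: int = 0,
                  feature_names=DEFAULT_VERIFY_FEATURES) -> pd.DataFrame:
    """Balanced expression/evolution comparison across three gene sets.

    The larger of the two called sets is downsampled (seeded, uniform) to
    the size of the smaller before testing, so group sizes are comparable.
    For each feature, reference-active, predicted-active and
    predicted-inactive genes are compared by Kruskal–Wallis followed by
    Dunn's pairwise tests with BH correction (applied per feature).
    Returns a long-format report with group means and adjusted p-values.
    """
    act = [g for g in called_active if g in features.index]
    inact = [g for g in called_inactive if g in features.index]
    ref = [g for g in reference_active_ids if g in features.index]
    if not act or not inact or not ref:
        raise EvaluationError("every comparison set must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(act), len(inact))
    if len(act) > n:
        act = list(rng.choice(act, size=n, replace=False))
    if len(inact) > n:
        inact = list(rng.choice(inact, size=n, replace=False))
    sets = {"reference_active": ref, "predicted_active": act,
            "predicted_inactive": inact}
    rows = []
    for feat in feature_names:
        groups = {name: features.loc[ids, feat].dropna().to_numpy()
                  for name, ids in sets.items()}
        if any(len(v) == 0 for v in groups.values()):
            continue
        res = kruskal_dunn_bh(list(groups.values()), labels=list(groups))
        means = {name: float(np.mean(v)) for name, v in groups.items()}
        for _, pr in res.pairwise.iterrows():
            rows.append({
                "feature": feat,
                "kw_statistic": res.statistic, "kw_p": res.pvalue,
                "group_i": pr["group_i"], "group_j": pr["group_j"],
                "mean_i": means[pr["group_i"]], "mean_j": means[pr["group_j"]],
                "dunn_z": pr["z"], "p_adj": pr["p_adj"],
            })
    report = pd.DataFrame(rows)
    report.attrs["downsample_seed"] = seed
    report.attrs["group_sizes"] = {k: len(v) for k, v in sets.items()}
    return report
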