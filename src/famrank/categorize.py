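"""Evidence-based group categorization and group-level statistics.

Genes are tiered by the strength of their functional evidence:

* Group I — the ubiquitylation substrate is characterized (well studied);
* Group II — a mutant phenotype is known but no substrate;
* Group III — reported as significantly differentially expressed in
  transcriptome-wide studies, nothing more;
* Group IV — never reported in any of the above.

The precedence is substrate > phenotype > differential expression: the tiers
are nested exclusions, so a gene with both a phenotype and a differential-
expression report is Group II.

Also houses the small-sample statistics the group comparisons rely on:
Fisher's exact test on 2×2 tables (two-sided, R-default "sum of
probabilities ≤ observed" convention), rare-domain overrepresentation, and
the Kruskal–Wallis test followed by Dunn's pairwise z tests with
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .feature_table import GROUPS

EVIDENCE_FLAGS = ["substrate_known", "interacts_ask1", "phenotype_known",
                  "de_reported"]


class CategorizationError(ValueError):
    pass


def assign_group(substrate_known, phenotype_known, de_reported,
                 interacts_ask1=False) -> str:
    """Tier one gene by evidence precedence substrate > phenotype > DE.

    ``interacts_ask1`` is descriptive evidence only and never changes the
    tier (all substrate-characterized members interact with the adaptor
    protein anyway).
    """
    if substrate_known:
        return "I"
    if phenotype_known:
        return "II"
    if de_reported:
        return "III"
    return "IV"


def assign_groups(evidence: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_group` over an evidence table."""
    sub = evidence["substrate_known"].astype(bool)
    phe = evidence["phenotype_known"].astype(bool)
    de = evidence["de_reported"].astype(bool)
    out = np.where(sub, "I", np.where(phe, "II", np.where(de, "III", "IV")))
    return pd.Series(out, index=evidence.index, name="group")


def summarize_groups(evidence: pd.DataFrame,
                     groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-group size and mean ± SD (sample SD) of the publication count."""
    if groups is None:
        groups = assign_groups(evidence)
    rows = []
    for g in GROUPS:
        vals = evidence.loc[groups == g, "n_publications"].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            rows.append((g, 0, np.nan, np.nan))
        else:
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            rows.append((g, n, float(np.mean(vals)), sd))
    return pd.DataFrame(rows, columns=["group", "n_genes", "mean_publications",
                                       "sd_publications"]).set_index("group")


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table.

    Returns the sample odds ratio ``(a·d)/(b·c)`` and the two-sided p-value
    obtained by summing hypergeometric probabilities no larger than that of
    the observed table (the R convention).  A zero margin makes the test
    degenerate: p = 1 and the odds ratio undefined (NaN).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise CategorizationError(f"need a non-negative 2x2 table, got {table!r}")
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def rare_ctd_overrepresentation(n_family_in_set: int, n_set: int,
                                n_family_total: int, n_proteome: int
                                ) -> tuple[float, float, float]:
    """Family overrepresentation among rare-domain-containing proteins.

    Compares the percentage of rare-CTD carriers that belong to the family
    against the family's background rate in the rest of the proteome; the
    p-value comes from :func:`fisher_exact` on the implied 2×2 table.
    Percentages are returned unrounded (round at display time).
    """
    if n_set <= 0:
        raise CategorizationError("n_set must be positive")
    if n_family_in_set > n_set or n_family_total > n_proteome:
        raise CategorizationError("subset counts exceed their totals")
    pct_set = 100.0 * n_family_in_set / n_set
    rest_family = n_family_total - n_family_in_set
    rest_total = n_proteome - n_set
    pct_background = 100.0 * rest_family / rest_total if rest_total > 0 else float("nan")
    table = [[n_family_in_set, n_set - n_family_in_set],
             [rest_family, rest_total - rest_family]]
    _, p = fisher_exact(table)
    return pct_set, pct_background, p


@dataclass
class KruskalDunnResult:
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group_i, group_j, z, p_raw, p_adj


def kruskal_dunn_bh(samples, labels=None) -> KruskalDunnResult:
    """Kruskal–Wallis rank-sum test plus Dunn's pairwise post-hoc tests.

    ``samples`` is a sequence of ≥2 non-empty 1-D arrays.  The KW statistic
    is tie-corrected; Dunn's z uses the pooled-rank variance with the usual
    tie correction and its two-sided p-values are adjusted across all pairs
    by Benjamini–Hochberg step-up.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise CategorizationError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise CategorizationError("every group must be non-empty")
    if labels is None:
        labels = [str(i + 1) for i in range(len(samples))]

    stat, p = scipy.stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    sizes = [len(s) for s in samples]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(samples))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0

    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p_raw, 1.0)))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_raw"])
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    return KruskalDunnResult(float(stat), float(p), pairwise)


def ctd_group_frequency(table: pd.DataFrame, ctd_columns,
                        groups: pd.Series | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group carrier frequency of each CTD class plus pairwise enrichment.

    Returns ``(freq, tests)``: ``freq`` is a groups × CTD grid of the
    proportion of genes carrying each domain class (a row for the whole
    family included as ``All``), and ``tests`` holds one Fisher enrichment
    test per CTD per ordered group pair.
    """
    if groups is None:
        groups = table["group"]
    freq_rows = {}
    for g in GROUPS:
        sub = table.loc[groups == g, ctd_columns]
        freq_rows[g] = (sub > 0).mean() if len(sub) else pd.Series(0.0, index=ctd_columns)
    freq_rows["All"] = (table[ctd_columns] > 0).mean() if len(table) else pd.Series(
        0.0, index=ctd_columns)
    freq = pd.DataFrame(freq_rows).T

    rows = []
    for ctd in ctd_columns:
        carrier = (table[ctd] > 0)
        for gi, gj in itertools.combinations(GROUPS, 2):
            in_i = groups == gi
            in_j = groups == gj
            t = [[int((carrier & in_i).sum()), int((~carrier & in_i).sum())],
                 [int((carrier & in_j).sum()), int((~carrier & in_j).sum())]]
            odds, p = fisher_exact(t)
            rows.append((ctd, gi, gj, odds, p))
    tests = pd.DataFrame(rows, columns=["ctd", "group_i", "group_j",
                                        "odds_ratio", "p"])
    return freq, tests
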