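"""Data model and I/O for the 27-characteristic gene feature table.

A feature table is a :class:`pandas.DataFrame` indexed by ``gene_id`` with a
``group`` column (evidence tier ``I``–``IV`` or ``unknown``) and 27 numeric
characteristics per gene: literature/clone counts, gene-structure counts,
T-DNA insertion counts by genomic region, molecular-evolution statistics
(Ka/Ks, Ks, a neutral-evolution flag), expression summaries derived from an
expression matrix, and C-terminal-domain (CTD) composition indicators.

On disk both the feature table and the expression matrix are UTF-8 TSV files
with a header row, the gene identifier in the first column and ``NA`` as the
missing-value token.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: T-DNA insertion counts by genomic region: 100 bp upstream of the
#: transcription start site, front/rear halves of the coding region and
#: front/rear halves of the non-coding region, plus their total.
TDNA_FEATURES = [
    "tdna_total",
    "tdna_upstream100",
    "tdna_coding_front",
    "tdna_coding_rear",
    "tdna_noncoding_front",
    "tdna_noncoding_rear",
]

COUNT_FEATURES = [
    "n_publications",
    "n_ESTs",
    "n_cDNAs",
    "n_introns",
    "n_exons",
    *TDNA_FEATURES,
]

EVOLUTION_FEATURES = ["ka_ks", "ks", "neutral_flag"]

EXPRESSION_FEATURES = ["expr_mean", "expr_median", "expr_max", "expr_cv"]

#: CTD composition indicators.  The four abundant substrate-binding domain
#: classes (LRR, Kelch, FBA, FBD) get individual indicators; TUB/WD40/DUF295
#: share one bucket and all rare domains another; plus the number of distinct
#: CTD classes, an F-box-domain presence flag and the F-box-domain HMM-hit
#: e-value exponent (log10 scale, more negative = stronger hit).
DOMAIN_FEATURES = [
    "ctd_lrr",
    "ctd_kelch",
    "ctd_fba",
    "ctd_fbd",
    "ctd_tub_wd40_duf295",
    "ctd_rare",
    "n_distinct_ctds",
    "has_fbxd",
    "fbxd_evalue_exp",
]

#: The full 27-characteristic schema.
FULL27 = COUNT_FEATURES + EVOLUTION_FEATURES + EXPRESSION_FEATURES + DOMAIN_FEATURES

#: The reduced feature set that best separates active from inactive genes.
REDUCED10 = [
    "n_publications",
    "n_ESTs",
    "n_cDNAs",
    "n_introns",
    "expr_mean",
    "expr_median",
    "expr_max",
    "expr_cv",
    "ks",
    "ka_ks",
]

FEATURE_SETS = {"full27": FULL27, "reduced10": REDUCED10}

GROUPS = ["I", "II", "III", "IV"]

MISSING_TOKEN = "NA"

# integer-valued columns (non-negative by contract)
_INT_FEATURES = COUNT_FEATURES + [
    "neutral_flag",
    "ctd_lrr",
    "ctd_kelch",
    "ctd_fba",
    "ctd_fbd",
    "ctd_tub_wd40_duf295",
    "ctd_rare",
    "n_distinct_ctds",
    "has_fbxd",
]


class FeatureTableError(ValueError):
    """Raised when a feature table violates its schema contract."""


def feature_set(name_or_members: str | Sequence[str]) -> list[str]:
    """Resolve a feature-set name (``full27``/``reduced10``) or explicit list."""
    if isinstance(name_or_members, str):
        try:
            return list(FEATURE_SETS[name_or_members])
        except KeyError:
            raise FeatureTableError(
                f"unknown feature set {name_or_members!r}; "
                f"expected one of {sorted(FEATURE_SETS)}"
            ) from None
    members = list(name_or_members)
    if not members:
        raise FeatureTableError("empty feature selection")
    return members


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check schema invariants, raising :class:`FeatureTableError` on violation.

    Checks: unique gene ids, presence of schema columns, non-negative integer
    counts, the T-DNA total equalling the sum of its five regions, and
    ``expr_max >= expr_median`` wherever both are present.
    """
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicate gene_id(s): {dup}")
    missing_cols = [c for c in FULL27 if c not in table.columns]
    if missing_cols:
        raise FeatureTableError(f"missing schema columns: {missing_cols}")
    for col in _INT_FEATURES:
        vals = table[col].dropna()
        if len(vals) == 0:
            continue
        if (vals < 0).any():
            bad = table.index[table[col] < 0][0]
            raise FeatureTableError(f"negative count in column {col!r} (gene {bad!r})")
        if not np.allclose(vals, np.round(vals)):
            bad = vals.index[~np.isclose(vals, np.round(vals))][0]
            raise FeatureTableError(
                f"non-integer count in column {col!r} (gene {bad!r})"
            )
    regions = table[TDNA_FEATURES[1:]].sum(axis=1)
    mismatch = ~np.isclose(table["tdna_total"], regions)
    if mismatch.any():
        bad = table.index[mismatch][0]
        raise FeatureTableError(
            f"tdna_total != sum of regional T-DNA counts for gene {bad!r}"
        )
    both = table[["expr_max", "expr_median"]].dropna()
    if (both["expr_max"] < both["expr_median"] - 1e-12).any():
        bad = both.index[both["expr_max"] < both["expr_median"] - 1e-12][0]
        raise FeatureTableError(f"expr_max < expr_median for gene {bad!r}")


def read_feature_table(path, validate: bool = True) -> pd.DataFrame:
    """Read a feature-table TSV; first column is ``gene_id``.

    Unknown columns are preserved as pass-through metadata.  Raises
    :class:`FeatureTableError` on duplicate ids or non-numeric feature cells
    (naming the offending row/column).
    """
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    table.index = table.index.astype(str)
    table.index.name = "gene_id"
    for col in table.columns:
        if col == "group":
            continue
        if col in FULL27 and not pd.api.types.is_numeric_dtype(table[col]):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = table.index[coerced.isna() & table[col].notna()]
            if len(bad):
                raise FeatureTableError(
                    f"non-numeric value in column {col!r} at gene {bad[0]!r}"
                )
            table[col] = coerced
    if validate:
        validate_feature_table(table)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV (``NA`` for missing values)."""
    table.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene_id")


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes × samples expression TSV (non-negative values)."""
    m = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    m.index = m.index.astype(str)
    m.index.name = "gene_id"
    if (m.fillna(0.0).to_numpy() < 0).any():
        raise FeatureTableError("expression matrix contains negative entries")
    return m


def write_expression_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene_id")


def summarize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression summaries: mean, median, max and CV over samples.

    CV is the sample standard deviation (ddof=1) divided by the mean; genes
    with mean 0 get a missing CV rather than an infinite one, and genes with
    all samples missing get all summaries missing (they are incomplete and
    will be removed by :func:`drop_incomplete`).
    """
    if matrix.shape[1] < 1:
        raise FeatureTableError("expression matrix needs at least one sample column")
    vals = matrix.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(vals, axis=1)
        median = np.nanmedian(vals, axis=1)
        mx = np.nanmax(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    out = pd.DataFrame(
        {"expr_mean": mean, "expr_median": median, "expr_max": mx, "expr_cv": cv},
        index=matrix.index,
    )
    return out


def is_complete(table: pd.DataFrame) -> pd.Series:
    """A record is complete iff none of its expression summaries is missing."""
    return table[EXPRESSION_FEATURES].notna().all(axis=1)


def drop_incomplete(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove records with missing expression summaries.

    Returns the retained table and the list of removed gene ids (also logged).
    """
    keep = is_complete(table)
    removed = table.index[~keep].tolist()
    if removed:
        logger.warning("removed %d incomplete gene(s): %s", len(removed), removed)
    if not keep.any():
        warnings.warn("all genes incomplete; resulting table is empty")
    return table.loc[keep].copy(), removed


def standardize(
    table: pd.DataFrame, features: str | Sequence[str] = "full27"
) -> pd.DataFrame:
    """Z-score the selected feature columns (mean 0, unit SD, ddof=0).

    Zero-variance columns map to all zeros with a warning.  Records must be
    complete for the selected features.
    """
    members = feature_set(features)
    X = table[members].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise FeatureTableError(
            f"cannot standardize with missing values in columns {bad}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero_var = sd <= 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance column(s) mapped to zeros: {sd.index[zero_var].tolist()}"
        )
    sd_safe = sd.where(~zero_var, 1.0)
    Z = (X - mean) / sd_safe
    Z.loc[:, zero_var] = 0.0
    return Z
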