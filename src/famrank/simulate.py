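"""Synthetic gene families with the statistical structure the pipeline assumes.

The generator emulates a large plant gene family (an F-box-like superfamily)
in which a minority of members is functionally active.  Truly active genes
are broadly expressed with low expression variability, sit under purifying
selection (low Ka/Ks, high Ks — old, constrained duplicates) and accumulate
literature and clone evidence; inactive members are rarely expressed (hence
a high expression CV), drift toward neutral Ka/Ks and carry little evidence.

A single ``separation`` knob multiplies the active-vs-inactive location shift
of every feature family: at ``separation=0`` the two generative distributions
are identical; at ``separation=1`` (default) group summaries match the
empirical means/SDs the analysis is calibrated to.

Randomness: one master seed spawns an independent substream per feature
family, so adding a feature never perturbs the draws of the others, and every
output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .feature_table import (
    DOMAIN_FEATURES,
    FULL27,
    summarize_expression,
)


class SimError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic family.

    Defaults emulate the study composition: 41 active-labeled (Group I),
    140 inactive-labeled (Group IV) and 511 unknown genes (of which a
    fraction is truly active; truly active unknowns may carry phenotype
    evidence and land in Group II, the rest in Group III).
    """

    n_active_labeled: int = 41
    n_inactive_labeled: int = 140
    n_unknown: int = 511
    frac_unknown_truly_active: float = 0.2
    n_expression_samples: int = 60
    separation: float = 1.0
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_active_labeled", "n_inactive_labeled", "n_unknown",
                     "n_expression_samples"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise SimError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("frac_unknown_truly_active", "label_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise SimError(f"{name} must be in [0, 1], got {v!r}")
        if self.separation < 0:
            raise SimError(f"separation must be >= 0, got {self.separation!r}")

    @property
    def n_genes(self) -> int:
        return self.n_active_labeled + self.n_inactive_labeled + self.n_unknown


class FamilyData(NamedTuple):
    """Outputs of :func:`generate_family`."""

    features: pd.DataFrame     # FULL27 schema + group column, indexed by gene_id
    expression: pd.DataFrame   # genes x samples, non-negative
    evidence: pd.DataFrame     # gene_id, flags, n_publications
    truth: pd.DataFrame        # gene_id, true_activity, assigned_group


# --- calibrated (separation = 1) parameter values ------------------------
# Expression: per-sample values are zero-inflated log-normal; pi is the
# probability a sample is silent (zero), mu/sigma the log-scale location
# and spread of expressed samples.
EXPR = dict(pi_active=0.05, pi_inactive=0.45, mu_active=2.5, mu_inactive=0.2,
            sigma=0.6)
# Ka/Ks: normal, clipped to (0.001, 1.5].  Active = purifying selection.
KAKS = dict(mu_active=0.23, mu_inactive=0.62, sd_active=0.11, sd_inactive=0.16)
# Ks: log-normal; active genes are older (whole-genome-duplication era) hence
# higher synonymous divergence.
KS = dict(logmu_active=np.log(1.8), logmu_inactive=np.log(0.55), logsd=0.5)
# Neutral-evolution flag probability.
NEUTRAL = dict(p_active=0.05, p_inactive=0.70)
# Gamma-Poisson (negative binomial) count families: (mean_active,
# mean_inactive, dispersion r); smaller r = more overdispersed.
COUNTS = {
    "n_ESTs": (40.0, 6.0, 1.2),
    "n_cDNAs": (12.0, 1.5, 1.5),
    "n_introns": (3.0, 1.2, 5.0),
}
# Publications track the evidence tier rather than activity alone: Group IV
# genes have, by definition, never been studied (mean exactly 0 at the
# calibrated separation).
PUBLICATIONS = dict(group_means={"I": 27.0, "II": 5.8, "III": 2.2, "IV": 0.0},
                    dispersion=0.3)
# Regional T-DNA insertion means (upstream100, coding front/rear,
# non-coding front/rear) for active genes; inactive = half.
TDNA = dict(active=(0.8, 2.5, 2.0, 1.2, 1.0), scale_inactive=0.5, dispersion=2.0)
# Primary CTD class probabilities (LRR, Kelch, FBA, FBD, TUB/WD40/DUF295
# bucket, rare bucket).
CTD = dict(p_active=(0.35, 0.30, 0.10, 0.05, 0.15, 0.05),
           p_inactive=(0.15, 0.05, 0.35, 0.25, 0.10, 0.10))
# F-box-domain HMM e-value exponent (log10): active hits are *weaker*
# (less negative) — domain strength does not track activity.
FBXD_EXP = dict(mu_active=-12.0, mu_inactive=-22.0, sd=5.0)

#: Probability that a truly active unknown gene carries phenotype evidence
#: (and therefore lands in Group II rather than Group III).
P_GROUP2_GIVEN_ACTIVE_UNKNOWN = 0.4

# fixed substream order; append-only so adding a feature never perturbs others
_STREAMS = ["truth", "publications", "n_ESTs", "n_cDNAs", "n_introns", "tdna",
            "ka_ks", "ks", "neutral", "domains", "expression", "evidence"]


def _lerp(active1: float, inactive1: float, sep: float) -> tuple[float, float]:
    """Interpolate class locations: identical at sep=0, calibrated at sep=1."""
    mid = 0.5 * (active1 + inactive1)
    return mid + sep * (active1 - mid), mid + sep * (inactive1 - mid)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _nbinom(rng, mean: np.ndarray, r: float) -> np.ndarray:
    """Gamma-Poisson mixture; mean 0 yields exact zeros."""
    mean = np.maximum(mean, 0.0)
    lam = rng.gamma(r, 1.0, size=mean.shape) * (mean / r)
    return rng.poisson(lam)


def generate_family(config: SimConfig) -> FamilyData:
    """Generate one synthetic family; deterministic given ``config.seed``."""
    n = config.n_genes
    sep = float(config.separation)
    rngs = _rngs(config.seed)
    gene_ids = pd.Index([f"G{i + 1:04d}" for i in range(n)], name="gene_id")

    if n == 0:
        features = pd.DataFrame(columns=["group"] + FULL27, index=gene_ids)
        expression = pd.DataFrame(
            index=gene_ids,
            columns=[f"S{j + 1:03d}" for j in range(config.n_expression_samples)],
            dtype=float,
        )
        evidence = pd.DataFrame(
            columns=["substrate_known", "interacts_ask1", "phenotype_known",
                     "de_reported", "n_publications"], index=gene_ids)
        truth = pd.DataFrame(columns=["true_activity", "assigned_group"],
                             index=gene_ids)
        return FamilyData(features, expression, evidence, truth)

    # --- ground truth and group assignment -------------------------------
    rng = rngs["truth"]
    active = np.zeros(n, dtype=bool)
    group = np.empty(n, dtype=object)
    a, b = config.n_active_labeled, config.n_inactive_labeled
    active[:a] = True
    group[:a] = "I"
    group[a:a + b] = "IV"
    u = rng.random(config.n_unknown) < config.frac_unknown_truly_active
    active[a + b:] = u
    g2 = rng.random(config.n_unknown) < P_GROUP2_GIVEN_ACTIVE_UNKNOWN
    group[a + b:] = np.where(u & g2, "II", "III")
    labeled = np.zeros(n, dtype=bool)
    labeled[:a + b] = True

    truth = pd.DataFrame(
        {"true_activity": np.where(active, "active", "inactive"),
         "assigned_group": group},
        index=gene_ids,
    )
    if config.label_noise_rate > 0:
        noise_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0]
                         % (2 ** 31))
        truth = inject_label_noise(truth, config.label_noise_rate, noise_seed)
        group = truth["assigned_group"].to_numpy()

    feats = pd.DataFrame(index=gene_ids)

    # --- publications (tier-driven) --------------------------------------
    gm = PUBLICATIONS["group_means"]
    mid = 0.5 * (gm["I"] + gm["IV"])
    pub_mean = np.array([max(0.0, mid + sep * (gm[g] - mid)) for g in group])
    feats["n_publications"] = _nbinom(rngs["publications"], pub_mean,
                                      PUBLICATIONS["dispersion"])

    # --- activity-driven count families ----------------------------------
    for name, (ma, mi, r) in COUNTS.items():
        m_act, m_inact = _lerp(ma, mi, sep)
        mean = np.where(active, max(m_act, 0.0), max(m_inact, 0.0))
        feats[name] = _nbinom(rngs[name], mean, r)
    feats["n_exons"] = feats["n_introns"] + 1

    # --- T-DNA insertions -------------------------------------------------
    rng = rngs["tdna"]
    regions = np.zeros((n, 5), dtype=int)
    for j, ma in enumerate(TDNA["active"]):
        mi = ma * TDNA["scale_inactive"]
        m_act, m_inact = _lerp(ma, mi, sep)
        mean = np.where(active, max(m_act, 0.0), max(m_inact, 0.0))
        regions[:, j] = _nbinom(rng, mean, TDNA["dispersion"])
    feats["tdna_total"] = regions.sum(axis=1)
    for j, col in enumerate(["tdna_upstream100", "tdna_coding_front",
                             "tdna_coding_rear", "tdna_noncoding_front",
                             "tdna_noncoding_rear"]):
        feats[col] = regions[:, j]

    # --- Ka/Ks, Ks, neutrality -------------------------------------------
    z = rngs["ka_ks"].standard_normal(n)
    mu_a, mu_i = _lerp(KAKS["mu_active"], KAKS["mu_inactive"], sep)
    sd_a, sd_i = _lerp(KAKS["sd_active"], KAKS["sd_inactive"], sep)
    mu = np.where(active, mu_a, mu_i)
    sd = np.maximum(np.where(active, sd_a, sd_i), 0.02)
    feats["ka_ks"] = np.clip(mu + sd * z, 0.001, 1.5)

    z = rngs["ks"].standard_normal(n)
    lmu_a, lmu_i = _lerp(KS["logmu_active"], KS["logmu_inactive"], sep)
    feats["ks"] = np.exp(np.where(active, lmu_a, lmu_i) + KS["logsd"] * z)

    p_a, p_i = _lerp(NEUTRAL["p_active"], NEUTRAL["p_inactive"], sep)
    p = np.clip(np.where(active, p_a, p_i), 0.0, 1.0)
    feats["neutral_flag"] = (rngs["neutral"].random(n) < p).astype(int)

    # --- CTD composition ---------------------------------------------------
    rng = rngs["domains"]
    pa = np.array(CTD["p_active"])
    pi_ = np.array(CTD["p_inactive"])
    mid_p = 0.5 * (pa + pi_)
    p_act = np.clip(mid_p + sep * (pa - mid_p), 1e-3, None)
    p_inact = np.clip(mid_p + sep * (pi_ - mid_p), 1e-3, None)
    p_act /= p_act.sum()
    p_inact /= p_inact.sum()
    u = rng.random(n)
    probs = np.where(active[:, None], p_act, p_inact)
    primary = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    for j, col in enumerate(DOMAIN_FEATURES[:6]):
        feats[col] = (primary == j).astype(int)
    feats["n_distinct_ctds"] = 1 + (rng.random(n) < 0.1).astype(int)
    feats["has_fbxd"] = 1
    z = rng.standard_normal(n)
    e_a, e_i = _lerp(FBXD_EXP["mu_active"], FBXD_EXP["mu_inactive"], sep)
    feats["fbxd_evalue_exp"] = np.where(active, e_a, e_i) + FBXD_EXP["sd"] * z

    # --- expression matrix and summaries ----------------------------------
    rng = rngs["expression"]
    ns = config.n_expression_samples
    z = rng.standard_normal((n, ns))
    u = rng.random((n, ns))
    pi_a, pi_i = _lerp(EXPR["pi_active"], EXPR["pi_inactive"], sep)
    mu_a, mu_i = _lerp(EXPR["mu_active"], EXPR["mu_inactive"], sep)
    pi_gene = np.clip(np.where(active, pi_a, pi_i), 0.005, 0.995)
    mu_gene = np.where(active, mu_a, mu_i)
    vals = np.where(u[:, :] < pi_gene[:, None], 0.0,
                    np.exp(mu_gene[:, None] + EXPR["sigma"] * z))
    expression = pd.DataFrame(
        vals, index=gene_ids, columns=[f"S{j + 1:03d}" for j in range(ns)])
    if ns > 0:
        feats = feats.join(summarize_expression(expression))
    else:
        for col in ["expr_mean", "expr_median", "expr_max", "expr_cv"]:
            feats[col] = np.nan

    features = pd.concat(
        [pd.Series(group, index=gene_ids, name="group"), feats[FULL27]], axis=1)

    # --- evidence ----------------------------------------------------------
    evidence = pd.DataFrame(
        {
            "substrate_known": (group == "I").astype(int),
            "interacts_ask1": (group == "I").astype(int),
            "phenotype_known": np.isin(group, ["I", "II"]).astype(int),
            "de_reported": np.isin(group, ["I", "II", "III"]).astype(int),
            "n_publications": feats["n_publications"].to_numpy(),
        },
        index=gene_ids,
    )
    return FamilyData(features, expression, evidence, truth)


def inject_label_noise(truth: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Flip each labeled gene's group (I↔IV) independently with ``rate``.

    Unknown genes (Groups II/III) and true activities are untouched; the
    result is a new truth table.
    """
    if not 0.0 <= rate <= 1.0:
        raise SimError(f"noise rate must be in [0, 1], got {rate!r}")
    out = truth.copy()
    labeled = out["assigned_group"].isin(["I", "IV"]).to_numpy()
    rng = np.random.default_rng(seed)
    flip = (rng.random(len(out)) < rate) & labeled
    g = out["assigned_group"].to_numpy(dtype=object).copy()
    g[flip] = np.where(g[flip] == "I", "IV", "I")
    out["assigned_group"] = g
    return out


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    t.index.name = "gene_id"
    return t
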