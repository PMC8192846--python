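import numpy as np
import pandas as pd
import pytest

from famrank.simulate import SimConfig, generate_family


@pytest.fixture(scope="session")
def small_family():
    """A well-separated small family shared by read-only tests."""
    cfg = SimConfig(n_active_labeled=15, n_inactive_labeled=45, n_unknown=60,
                    n_expression_samples=40, separation=3.0, seed=11)
    return generate_family(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_feature_row(**overrides):
    """A single schema-complete feature row for hand-built fixtures."""
    row = {
        "n_publications": 1, "n_ESTs": 2, "n_cDNAs": 1, "n_introns": 1,
        "n_exons": 2, "tdna_total": 3, "tdna_upstream100": 1,
        "tdna_coding_front": 1, "tdna_coding_rear": 1,
        "tdna_noncoding_front": 0, "tdna_noncoding_rear": 0,
        "ka_ks": 0.3, "ks": 1.0, "neutral_flag": 0,
        "expr_mean": 5.0, "expr_median": 4.0, "expr_max": 10.0, "expr_cv": 0.5,
        "ctd_lrr": 1, "ctd_kelch": 0, "ctd_fba": 0, "ctd_fbd": 0,
        "ctd_tub_wd40_duf295": 0, "ctd_rare": 0, "n_distinct_ctds": 1,
        "has_fbxd": 1, "fbxd_evalue_exp": -15.0,
    }
    row.update(overrides)
    return row


def make_feature_table(n, **common):
    rows = [make_feature_row(**common) for _ in range(n)]
    columns = list(make_feature_row())
    table = pd.DataFrame(rows, columns=columns,
                         index=pd.Index([f"G{i:03d}" for i in range(n)],
                                        name="gene_id"))
    return table
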