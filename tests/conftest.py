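import numpy as np
import pandas as pd
import pytest

from mrscreen.gwas_io import HarmonizedPair, SummaryStatsTable


def make_table(trait_id="exp", trait_class="gut_microbiota", rows=None, n_default=10_000):
    if rows is None:
        rows = [
            ("rs1", "A", "G", 0.30, 0.10, 0.020, 5.6e-7, 10_000),
            ("rs2", "T", "C", 0.45, -0.08, 0.018, 8.8e-6, 10_000),
            ("rs3", "G", "A", 0.12, 0.15, 0.030, 5.7e-7, 10_000),
        ]
    df = pd.DataFrame(rows, columns=["SNP", "effect_allele", "other_allele",
                                     "eaf", "beta", "se", "pval", "n"])
    return SummaryStatsTable(trait_id=trait_id, trait_class=trait_class, df=df,
                             n_default=n_default)


def make_pair(gamma, se_gamma, Gamma, se_Gamma, n_exp=50_000, n_out=100_000):
    j = len(gamma)
    return HarmonizedPair(
        variant_ids=[f"rs{i + 1}" for i in range(j)],
        gamma=np.asarray(gamma, float),
        se_gamma=np.asarray(se_gamma, float),
        Gamma=np.asarray(Gamma, float),
        se_Gamma=np.asarray(se_Gamma, float),
        eaf=np.full(j, 0.3),
        exposure_n=np.full(j, float(n_exp)),
        outcome_n=np.full(j, float(n_out)),
    )


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def homogeneous_pair():
    """Five instruments whose Wald ratios are all exactly 0.3."""
    g = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
    return make_pair(g, np.full(5, 0.02), 0.3 * g, np.full(5, 0.01))


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)
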