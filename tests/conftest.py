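import numpy as np
import pandas as pd
import pytest

import mirlink as ml


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across read-only tests."""
    cfg = ml.CohortConfig(
        n_samples=40, n_mirna=20, n_mrna=300, frac_true_pairs=0.02,
        n_intragenic=5, seed=1,
    )
    mirna, mrna, truth = ml.generate_paired_cohort(cfg)
    return cfg, mirna, mrna, truth


@pytest.fixture(scope="session")
def small_corr(small_cohort):
    """Correlation table for the small cohort on log2(CPM + 1)."""
    _cfg, mirna, mrna, _truth = small_cohort
    mir_l2 = np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mirna.counts)) + 1)
    mrna_l2 = np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mrna.counts)) + 1)
    return ml.all_pairs_pearson(mir_l2, mrna_l2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def counts_frame(values, features=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)
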