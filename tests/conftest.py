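import numpy as np
import pandas as pd
import pytest

from cllnet.synthetic import generate_truth, simulate_cohort, simulate_survival


@pytest.fixture(scope="session")
def small_truth():
    """10 TFs x 15 targets with 20% shared-pool overlap, 60 DE genes."""
    return generate_truth(
        n_genes=160, n_tfs=10, targets_per_tf=15, overlap_fraction=0.2,
        n_de=60, n_survival=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return simulate_cohort(
        small_truth, n_mut=60, n_unmut=60, group_shift=1.5, noise_sd=1.0,
        seed=21, cohort_id="T1",
    )


@pytest.fixture(scope="session")
def survival_cohort(small_truth, small_cohort):
    return simulate_survival(
        small_cohort, small_truth, baseline_rate=0.1, censor_rate=0.05, seed=31
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def iid_expr(rng):
    """Independent Gaussian expression: 80 genes x 60 samples."""
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(80, 60)),
        index=[f"g{i:03d}" for i in range(80)],
        columns=[f"s{i:03d}" for i in range(60)],
    )
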