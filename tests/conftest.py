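import warnings

import numpy as np
import pandas as pd
import pytest

import promclock as pc

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cfg():
    return pc.SimulationConfig(
        n_samples=20,
        n_promoters=40,
        n_causal=6,
        effect_sd=0.03,
        cpgs_per_promoter=(10, 15),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return pc.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return pc.simulate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cfg, small_cohort, small_annotation):
    promoters, catalogue = small_annotation
    m, truth = pc.simulate_site_matrix(small_cohort, promoters, catalogue, small_cfg)
    return m, truth


@pytest.fixture(scope="session")
def small_promoter_matrix(small_cfg, small_matrix, small_annotation):
    m, _ = small_matrix
    promoters, _ = small_annotation
    filtered, _ = pc.filter_cpgs_by_coverage(m)
    windows = pc.assign_sites_to_windows(filtered, pc.expand_windows(promoters))
    return pc.aggregate(filtered, windows), filtered, windows


def random_promoter_matrix(rng, n_samples, n_promoters, with_imputed=False):
    """Small random PromoterMatrix for oracle tests."""
    values = rng.random((n_samples, n_promoters))
    imputed = None
    if with_imputed:
        imputed = rng.random((n_samples, n_promoters)) < 0.05
    return pc.PromoterMatrix(
        promoter_ids=[f"P{j}" for j in range(n_promoters)],
        sample_ids=[f"S{i}" for i in range(n_samples)],
        values=values,
        n_cpgs=np.full(n_promoters, 10),
        genes=[f"G{j}" for j in range(n_promoters)],
        imputed=imputed,
    )


def random_covariates(rng, sample_ids):
    data = pd.DataFrame(
        {
            "age": rng.uniform(20, 95, len(sample_ids)),
            "sex": rng.integers(0, 2, len(sample_ids)),
            "pmi": rng.lognormal(3.0, 0.4, len(sample_ids)),
            "pmi_imputed": False,
        },
        index=pd.Index(list(sample_ids), name="sample_id"),
    )
    return pc.CovariateTable(data=data, sex_mapping={"F": 0, "M": 1})
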