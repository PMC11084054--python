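import numpy as np
import pandas as pd
import pytest

from lvddlink import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """Reduced-scale cohort settings for fast tests."""
    base = dict(
        n=400,
        n_species=60,
        n_metabolites=80,
        n_kos=120,
        seq_depth=20_000,
        ko_depth=40_000,
        n_structural_zero_species=2,
        n_extra_assoc_metabolites=30,
        kos_per_proxy_species=10,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(), seed=7)


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-scale cohort shared across the slower tests."""
    from lvddlink import default_paper_scale
    return generate_cohort(default_paper_scale(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_table(values, kind="counts", prefix="f"):
    """Helper: FeatureTable from a 2-D array."""
    from lvddlink import FeatureTable
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )
    return FeatureTable(df, kind)
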