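import numpy as np
import pandas as pd
import pytest

from burdenmeta.annotation import classify_variants
from burdenmeta.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A quick cohort: 200+200 samples, 30 genes, deterministic seed."""
    return SimulationConfig(
        n_cases=200, n_controls=200, n_genes=30, constrained_fraction=0.5,
        rare_allele_freq_range=(5e-4, 5e-3), n_common_snps=120,
        per_call_depth=True, missing_rate=0.02, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = simulate_cohort(small_config)
    cohort.variants = classify_variants(cohort.variants)
    return cohort


@pytest.fixture()
def toy_genotypes():
    """10 samples x 6 variants with hand-checkable dosages."""
    rng = np.random.default_rng(5)
    dosages = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    depths = rng.integers(20, 80, size=(10, 6)).astype(np.int32)
    return dosages, depths
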