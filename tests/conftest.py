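import numpy as np
import pandas as pd
import pytest

from dynapred.simulate import ClinicalVar, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Desk-scale cohort with the default generating mechanism."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, 50 genes (4 causal) - fast enough for pipeline runs."""
    return simulate_cohort(
        SimConfig(n_subjects=60, n_genes=50, n_causal_genes=4,
                  gene_effect_sizes=(0.6, 0.6, -0.6, -0.6), seed=7)
    )


@pytest.fixture(scope="session")
def clinical_only_config():
    """Generator config with no gene signal and a single prognostic score."""
    return SimConfig(
        n_subjects=400, n_genes=2, n_causal_genes=0, gene_effect_sizes=(),
        clinical_spec=[ClinicalVar("risk_score", "continuous", 0.8)],
        seed=0,
    )


def exponential_cohort(rng, n, beta=0.0, censor_scale=None):
    """Simple exponential-baseline cohort for closed-form checks."""
    x = rng.normal(size=n)
    T = rng.exponential(np.exp(-beta * x), size=n)
    if censor_scale is None:
        return x, T, np.ones(n, dtype=int)
    C = rng.exponential(censor_scale, size=n)
    return x, np.minimum(T, C), (T <= C).astype(int)
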