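import numpy as np
import pandas as pd
import pytest

from eduwas.synth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_cpgs=300, n_causal=60, n_smoking_only=60, seed=11)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    """One synthetic cohort (samples, methylation, truth) reused across tests."""
    return generate_cohort(small_cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_samples():
    """Hand-sized sample table with every modelling column populated."""
    g = np.random.default_rng(7)
    n = 80
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "family_id": [f"f{i:03d}" for i in range(n)],
        "sex": g.choice(["F", "M"], size=n),
        "birth_year": g.integers(1940, 1990, size=n),
        "age": g.uniform(25, 70, size=n).round(1),
        "bmi": g.uniform(19, 33, size=n).round(1),
        "education_category": g.integers(1, 8, size=n),
        "education_ridit": g.uniform(0.02, 0.98, size=n),
        "smoking_status": g.choice(["never", "former", "current"], size=n),
        "cotinine": g.uniform(0, 30, size=n).round(2),
        "neutrophil_pct": g.uniform(40, 70, size=n).round(1),
        "monocyte_pct": g.uniform(4, 12, size=n).round(1),
        "eosinophil_pct": g.uniform(0.5, 6, size=n).round(1),
        "plate": g.choice(["P1", "P2"], size=n),
        "array_row": g.choice(["R1", "R2", "R3"], size=n),
    })
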