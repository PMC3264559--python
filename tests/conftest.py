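import numpy as np
import pandas as pd
import pytest

from gsvdcna import PairedGSVD, SimulationConfig, simulate_cohort
from gsvdcna.preprocess import preprocess_pair


def toy_probes(chromosomes=("1", "2", "3", "X"), n_per=12, p_fraction=0.5):
    """Small probe table in genome order, equal probes per chromosome."""
    rows = []
    n_p = int(round(p_fraction * n_per))
    for c in chromosomes:
        for i in range(n_per):
            rows.append(
                {
                    "probe_id": f"p_{c}_{i}",
                    "chromosome": c,
                    "arm": "p" if i < n_p else "q",
                    "start": 1000 * (i + 1),
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated 80-patient cohort shared by the slower tests."""
    cfg = SimulationConfig(n_patients=80, seed=11)
    tumor, normal, clinical, truth = simulate_cohort(cfg)
    return cfg, tumor, normal, clinical, truth


@pytest.fixture(scope="session")
def small_fact(small_cohort):
    """The paired decomposition of the shared cohort."""
    _, tumor, normal, clinical, truth = small_cohort
    paired, tumor_p, normal_p = preprocess_pair(tumor, normal)
    fact = PairedGSVD().fit(paired)
    return fact, tumor_p, normal_p, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
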