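import numpy as np
import pandas as pd
import pytest

import mireqtl as m
from mireqtl.synth import cis_candidate_pairs

# the planted-effect study scenario shared by the pipeline-level tests:
# a 197-patient cohort with 6 causal SNP-miRNA pairs of moderate effect
PLANTED = dict(
    n_snps=150, n_mirnas=24, n_causal_pairs=6, eqtl_slope=1.5, pair_beta=0.2
)


def planted_scenario(seed: int):
    """Simulate the planted-effect cohort plus its cis eQTL scan source."""
    config = m.SimulationConfig(seed=seed, **PLANTED)
    sim = m.simulate_cohort(config)
    candidates = cis_candidate_pairs(
        sim.genotypes, sim.expression, sim.truth, per_mirna=5, seed=seed
    )
    source = m.EqtlScanSource(n_perm=199, seed=seed, candidate_pairs=candidates)
    return sim, source


@pytest.fixture
def empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["snp", "mirna", "slope", "p_nominal", "p_adjusted"])


@pytest.fixture
def toy_survival() -> pd.DataFrame:
    """Small mixed cohort with events, censoring and score ties."""
    rng = np.random.default_rng(42)
    n = 40
    return pd.DataFrame(
        {
            "age": rng.normal(75, 5, n),
            "sex": rng.integers(0, 2, n),
            "apoe4": rng.integers(0, 3, n),
            "time": rng.uniform(100, 2000, n),
            "event": rng.integers(0, 2, n),
        },
        index=[f"S{i:03d}" for i in range(n)],
    )
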