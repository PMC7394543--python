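import numpy as np
import pandas as pd
import pytest

from twinlipid.synthetic_data import (
    SyntheticConfig,
    simulate_twin_cohort,
    simulate_expression,
    simulate_methylation,
)
from twinlipid import twin_models as tm


@pytest.fixture(scope="session")
def big_cohort():
    """5000 MZ + 5000 DZ pairs of one lipid with a2=0.5, c2=0.2."""
    cfg = SyntheticConfig(
        n_mz_pairs=5000, n_dz_pairs=5000, n_lipids=1, a2=0.5, c2=0.2, e2=0.3,
        seed=101,
    )
    cohort, truth = simulate_twin_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def big_pairs(big_cohort):
    cohort, truth = big_cohort
    return tm.TwinPairs(tm.pairs_from_members(cohort, cohort[truth.lipid_names[0]]))


@pytest.fixture(scope="session")
def small_omics():
    """100-member cohort with expression (planted hits) and methylation."""
    cfg = SyntheticConfig(
        n_mz_pairs=25, n_dz_pairs=25, n_lipids=3, n_probes=40, n_cpg=50,
        planted_assoc=[(0, 5, 1.0), (1, 9, -0.8)], probe_noise_sd=0.5,
        gwam_beta=-0.4, seed=202,
    )
    cohort, truth = simulate_twin_cohort(cfg)
    expression = simulate_expression(cohort, truth, cfg)
    methylation = simulate_methylation(cohort, truth, cfg)
    return cfg, cohort, truth, expression, methylation
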