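import numpy as np
import pandas as pd
import pytest

from casekit import SimParams, build_observation_table, default_design, filter_sites, simulate_counts, simulate_truth


@pytest.fixture(scope="session")
def small_design():
    """2 individuals x 3 cell types x 14 conditions x 2 plates."""
    return default_design(n_individuals=2)


@pytest.fixture(scope="session")
def null_obs():
    """Observation table from the null generator (no effects), 6 units."""
    params = SimParams(n_snps=6, n_individuals=1, prop_base=0.0, sigma_resid=0.0,
                       depth_mean=200.0, seed=42)
    truth = simulate_truth(params)
    counts = simulate_counts(truth)
    return build_observation_table(filter_sites(counts))


@pytest.fixture(scope="session")
def effect_obs():
    """Observation table where every SNP carries baseline imbalance."""
    params = SimParams(n_snps=6, n_individuals=1, prop_base=1.0, sd_base=1.0,
                       sigma_resid=0.1, depth_mean=300.0, seed=7)
    truth = simulate_truth(params)
    counts = simulate_counts(truth)
    return truth, build_observation_table(filter_sites(counts))


def toy_group(values_by_condition):
    """Observation table for one unit from {(cell, treatment, vehicle, plate): [ase...]}."""
    rows = []
    for (cell, treat, veh, plate), values in values_by_condition.items():
        for v in values:
            rows.append(
                {"snp_id": "s1", "individual": "i1", "cell_type": cell,
                 "treatment": treat, "vehicle": veh, "plate": plate,
                 "ase": float(v), "coverage": 50}
            )
    return pd.DataFrame(rows)
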