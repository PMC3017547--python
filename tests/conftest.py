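import math

import pytest

import imprintarray as ia


# keeps the imprinted-probe share near the real array's ~4% so correlation
# structure (shared ESC signature vs phESC DMR divergence) stays realistic
SMALL = dict(n_probes=600, n_imprinted_genes=8, probes_per_imprinted_gene=3)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Small dataset with no probe-level noise (kappa infinite)."""
    cfg = ia.SimulationConfig(seed=101, kappa=math.inf, **SMALL)
    return ia.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small dataset at high concentration (low noise)."""
    cfg = ia.SimulationConfig(seed=202, kappa=300.0, **SMALL)
    return ia.simulate_dataset(cfg)


def run_pipeline(dataset, t_low=0.3, t_high=0.7, eps_range=0.3):
    """Full beta -> normalize -> aggregate -> call chain (shared helper)."""
    beta = ia.compute_beta(dataset.signals)
    profile = ia.build_control_profile(beta, dataset.samples, eps_range=eps_range)
    normalized = ia.range_scale_normalize(beta, profile)
    line_beta = ia.aggregate_replicates(normalized, dataset.samples)
    states = ia.call_states(line_beta, t_low=t_low, t_high=t_high)
    return beta, profile, normalized, line_beta, states


@pytest.fixture(scope="session")
def noisefree_pipeline(noisefree_dataset):
    return run_pipeline(noisefree_dataset)


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_dataset):
    return run_pipeline(noisy_dataset)
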