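import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_trajectory():
    """Four genes (one per family) along a 150-cell trajectory, phi = 10."""
    import cascadefit as cf

    specs = cf.benchmark_gene_specs(1, 150, seed=17)
    cfg = cf.SimulationConfig(n_cells=150, phi=10.0, gene_specs=specs, seed=4)
    cm, pt, truth = cf.make_benchmark_dataset(cfg)
    return cf.build_trajectory(cm, pt), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
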