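import numpy as np
import pytest

from mztseq import ClusterSpec, SimulationConfig, simulate_timecourse


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def planted_timecourse():
    """Small two-class time course with nulls, shared across tests."""
    cfg = SimulationConfig(
        n_genes=30,
        cluster_spec=[
            ClusterSpec("U1", 8, "maternal_decay", onset=2.0, effect=6.0),
            ClusterSpec("D1", 8, "zygotic_sigmoid", onset=4.0, effect=0.2),
        ],
        noise_cv=0.1,
        seed=42,
        library_types=("polyA+", "ribozero"),
    )
    datasets, truth = simulate_timecourse(cfg)
    return cfg, datasets, truth
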