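import numpy as np
import pytest

from regdiv.simulate import (
    SimulationConfig,
    TruthRecord,
    generate_truth,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=30, seed=42, base_expression_mean=80.0)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def hybrid_read_sim(small_truth, small_config):
    return simulate_reads(small_truth, small_config, kind="hybrid")


@pytest.fixture(scope="session")
def varied_cis_truth():
    """Genes with a spread of cis effects and no trans effect."""
    rng = np.random.default_rng(7)
    out = []
    for i in range(50):
        c = float(rng.uniform(-2.0, 2.0))
        cat = "cis" if abs(c) > 0 else "conserved"
        out.append(TruthRecord(f"vg{i:03d}", cat if c != 0 else "conserved", c, 0.0))
    return out
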