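import numpy as np
import pytest

from grnbench import (ExpressionMatrix, ExperimentDesign, SimulatorParams,
                      generate_source_network, sample_subnetwork,
                      simulate_experiments, to_undirected_truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples with simple structure."""
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [2.0, 4.0, 6.0, 8.0],
                       [4.0, 3.0, 2.0, 1.0]])
    return ExpressionMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture(scope="session")
def random_expr():
    """Seeded 10-gene x 12-sample random matrix for smoke/property tests."""
    r = np.random.default_rng(7)
    values = r.uniform(0.1, 2.0, size=(10, 12))
    return ExpressionMatrix([f"g{i}" for i in range(10)],
                            [f"s{k}" for k in range(12)], values)


@pytest.fixture(scope="session")
def source_net():
    return generate_source_network(120, 3.0, seed=11)


@pytest.fixture(scope="session")
def sim_knockout(source_net):
    """30-node knockout benchmark instance (matrix, truth)."""
    sub = sample_subnetwork(source_net, 30, seed=5)
    X, net = simulate_experiments(sub, ExperimentDesign("knockout", 30),
                                  SimulatorParams(seed=17))
    return X, to_undirected_truth(net)


@pytest.fixture(scope="session")
def sim_multifactorial(source_net):
    sub = sample_subnetwork(source_net, 20, seed=6)
    X, net = simulate_experiments(sub, ExperimentDesign("multifactorial", 25),
                                  SimulatorParams(seed=18))
    return X, to_undirected_truth(net)
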