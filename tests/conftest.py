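import pytest

import diagcea as d


@pytest.fixture(scope="session")
def table1_params():
    """DD&MCA point estimates (costs in USD, times in weeks)."""
    return d.params_point("table1")


@pytest.fixture(scope="session")
def table3_specs():
    """DD&MCA Monte Carlo parameter distributions."""
    return d.default_params("table3")


@pytest.fixture(scope="session")
def table5_params():
    """Structural-heart-disease constants."""
    return d.params_point("table5")


@pytest.fixture(scope="session")
def config():
    return d.default_config()


@pytest.fixture()
def single_exit_tree():
    return d.DiagnosticTree.build([d.Node("root", "exit")], [], "root")


@pytest.fixture()
def three_node_tree():
    """Root action (cost 10) splitting 0.3/0.7 to exits costing 20 and 30."""
    nodes = [
        d.Node("r", "action", base_cost=10.0),
        d.Node("a", "exit", base_cost=20.0),
        d.Node("b", "exit", base_cost=30.0),
    ]
    edges = [
        d.Transition("r", "a", 0.3, "empirical"),
        d.Transition("r", "b", 0.7, "empirical"),
    ]
    return d.DiagnosticTree.build(nodes, edges, "r")
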