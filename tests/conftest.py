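import pytest

from cfpath import CfpSolver, connectivity_curve, toy_network


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def toy_solver(toy):
    net, arcs = toy
    return CfpSolver(net, arcs)


@pytest.fixture(scope="session")
def toy_wild_curve(toy, toy_solver):
    net, arcs = toy
    return connectivity_curve(net, arcs, "G6P", solver=toy_solver)
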