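import pytest

from medianet import InteractionNetwork, toy_fixture, random_disease_network


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def toy_net(toy):
    return toy.network


@pytest.fixture
def path_abc():
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")], name="path3")


@pytest.fixture
def star5():
    """K_{1,4}: hub 'c' with four leaves."""
    return InteractionNetwork.from_edges(
        [("c", f"l{k}") for k in range(4)], name="star"
    )


@pytest.fixture(scope="session")
def random_cases():
    """A batch of small seeded random networks for property checks."""
    cases = []
    for seed in range(12):
        n = 5 + seed % 6
        p = 0.2 if seed % 2 else 0.5
        cases.append(random_disease_network(n, p, ["X", "Y"], 1, seed=seed))
    return cases
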