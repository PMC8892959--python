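import pytest

from quantrange import fixtures as fx

#: Size of the random-instance battery used by the equivalence suites.
BATTERY_SEEDS = range(200)


def make_instance(seed: int) -> fx.FlowFixture:
    """Small random flow DAG (<=10 vertices) deterministic in ``seed``."""
    return fx.random_flow_dag(
        n_vertices=3 + seed % 8,
        edge_density=0.3 + 0.05 * (seed % 5),
        n_paths=1 + seed % 5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def battery():
    """The shared 200-instance battery of random flow DAGs."""
    return [make_instance(seed) for seed in BATTERY_SEEDS]


@pytest.fixture(scope="session")
def w_graph():
    return fx.w_graph_fixture()


@pytest.fixture(scope="session")
def transcriptome():
    return fx.synthetic_transcriptome(n_genes=20, isoforms_per_gene=3, seed=7)
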