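import pytest

from ben4topo import ben4_edge_partition, ben4_vertex_partition


@pytest.fixture(scope="session")
def diagonal_grid():
    return [(i, i) for i in range(1, 11)]


@pytest.fixture
def unit_cell_partitions():
    """Vertex and edge partition of the single-unit-cell sheet (m=n=1)."""
    return ben4_vertex_partition(1, 1), ben4_edge_partition(1, 1)
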