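"""Degree-level description of BeN4 and of arbitrary simple graphs."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ben4topo import (
    ben4_counts,
    ben4_edge_partition,
    ben4_vertex_partition,
    make_graph,
    partition_frame,
    partitions_from_graph,
    read_edge_list,
    validate_partitions,
    write_edge_list,
)


@pytest.mark.parametrize(
    "m, n, expected",
    [((1), 1, (8, 7)), (10, 10, (521, 790)), (3, 2, (36, 46))],
)
def test_ben4_counts(m, n, expected):
    assert ben4_counts(m, n) == expected


@pytest.mark.parametrize(
    "m, n, expected",
    [
        (1, 1, {1: 4, 2: 2, 3: 2, 4: 0}),
        (2, 2, {1: 4, 2: 8, 3: 12, 4: 1}),
    ],
)
def test_vertex_partition_values(m, n, expected):
    assert ben4_vertex_partition(m, n) == expected


def test_vertex_partition_total_matches_counts():
    for m in range(1, 21):
        for n in range(1, 21):
            assert sum(ben4_vertex_partition(m, n).values()) == ben4_counts(m, n)[0]


def test_edge_partition_unit_cell():
    assert ben4_edge_partition(1, 1) == {
        (1, 2): 2, (1, 3): 2, (2, 2): 0, (2, 3): 2, (3, 3): 1, (3, 4): 0,
    }


def test_edge_partition_total_and_34_factorisation():
    # (3,4)-class count is 4(m-1)(n-1); totals follow the edge-count formula
    for m in range(1, 21):
        for n in range(1, 21):
            ep = ben4_edge_partition(m, n)
            assert sum(ep.values()) == ben4_counts(m, n)[1]
            assert ep[(3, 4)] == 4 * (m - 1) * (n - 1)
    assert ben4_edge_partition(3, 2)[(3, 4)] == 8


def test_edge_partition_freq33_override():
    ep = ben4_edge_partition(3, 3, freq33=lambda m, n: 4 * m * n - 4 * n)
    assert ep[(3, 3)] == 24
    assert ben4_edge_partition(3, 3, freq33=5)[(3, 3)] == 5
    with pytest.raises(ValueError):
        ben4_edge_partition(1, 1, freq33=-1)


def test_class_counts_nondecreasing_in_m_and_n():
    for m in range(1, 20):
        for n in range(1, 20):
            ep = ben4_edge_partition(m, n)
            for dm, dn in ((1, 0), (0, 1)):
                bigger = ben4_edge_partition(m + dm, n + dn)
                assert all(bigger[k] >= ep[k] for k in ep)


@pytest.mark.parametrize("bad", [(0, 1), (1, 0), (-2, 3), (1.5, 2), ("2", 2), (True, 1)])
def test_grid_validation_rejects(bad):
    with pytest.raises((ValueError, TypeError)):
        ben4_counts(*bad)


@pytest.mark.parametrize(
    "graph, vp, ep",
    [
        (nx.cycle_graph(5), {2: 5}, {(2, 2): 5}),
        (nx.star_graph(4), {1: 4, 4: 1}, {(1, 4): 4}),
        (nx.complete_graph(4), {3: 4}, {(3, 3): 6}),
    ],
)
def test_partitions_from_classic_graphs(graph, vp, ep):
    got_vp, got_ep = partitions_from_graph(graph)
    assert got_vp == vp
    assert got_ep == ep


def test_partitions_from_graph_rejects_self_loops():
    g = nx.Graph([(1, 2), (2, 2)])
    with pytest.raises(ValueError, match="self-loop"):
        partitions_from_graph(g)


def test_validate_partitions_ben4_consistent_up_to_20():
    # handshake and second-moment identities hold for every m, n <= 20
    for m in range(1, 21):
        for n in range(1, 21):
            report = validate_partitions(
                ben4_vertex_partition(m, n), ben4_edge_partition(m, n)
            )
            assert report.passed, (m, n, report.checks, report.details)


def test_validate_partitions_flags_handshake_failure():
    report = validate_partitions({2: 3}, {(2, 2): 2})
    assert not report.checks["handshake"]
    assert not report.passed


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 30))
def test_random_graph_partitions_validate(seed, n):
    g = make_graph("random", n, edge_probability=0.35, seed=seed)
    vp, ep = partitions_from_graph(g)
    assert sum(vp.values()) == g.number_of_nodes()
    assert sum(ep.values()) == g.number_of_edges()
    assert validate_partitions(vp, ep).passed


def test_edge_list_round_trip(tmp_path):
    g = make_graph("random", 15, edge_probability=0.3, seed=11)
    path = tmp_path / "g.edges"
    write_edge_list(g, path)  # 0-based generator labels get shifted to 1-based
    back = read_edge_list(path)
    vp1, ep1 = partitions_from_graph(g)
    vp2, ep2 = partitions_from_graph(back)
    assert (vp1, ep1) == (vp2, ep2)


@pytest.mark.parametrize(
    "content, message",
    [
        ("1 2\n1 2\n", "duplicate"),
        ("1 1\n", "self-loop"),
        ("1 2 3\n", "two vertex ids"),
        ("0 2\n", ">= 1"),
        ("a b\n", "non-integer"),
    ],
)
def test_edge_list_rejects_malformed(tmp_path, content, message):
    path = tmp_path / "bad.edges"
    path.write_text("# comment line\n\n" + content)
    with pytest.raises(ValueError, match=message):
        read_edge_list(path)


def test_edge_list_ignores_comments_and_blanks(tmp_path):
    path = tmp_path / "ok.edges"
    path.write_text("# header\n\n1 2\n2 3\n")
    g = read_edge_list(path)
    assert sorted(g.edges()) == [(1, 2), (2, 3)]


def test_partition_frame_layout(unit_cell_partitions):
    vp, ep = unit_cell_partitions
    f = partition_frame(ep)
    assert list(f.columns) == ["class", "count"]
    assert f["count"].sum() == 7
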