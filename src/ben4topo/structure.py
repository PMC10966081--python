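"""Degree-level description of the beryllonitrene BeN4(m, n) network.

Beryllonitrene is a planar beryllium--nitrogen sheet.  For a patch of
``m`` x ``n`` unit cells its molecular graph has ``5mn + m + n + 1``
vertices and ``8mn - n`` edges.  Because every topological index treated
in this package is degree-based, the sheet is fully characterised by two
small summaries:

* the *vertex partition* -- how many vertices carry each degree, and
* the *edge partition* -- how many edges join each unordered pair of
  endpoint degrees.

This module produces those partitions from closed-form counting
formulas, derives the same summaries from any explicit simple graph, and
audits their internal consistency (handshake and second-moment checks).

Degree pairs are unordered and stored min-first: every edge weight used
downstream is symmetric in the two endpoint degrees, so ``(a, b)`` and
``(b, a)`` describe the same edge class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import pandas as pd

__all__ = [
    "ben4_counts",
    "ben4_vertex_partition",
    "ben4_edge_partition",
    "partitions_from_graph",
    "validate_partitions",
    "ValidationReport",
    "read_edge_list",
    "write_edge_list",
    "partition_frame",
]

#: type alias -- degree -> number of vertices with that degree
VertexPartition = dict[int, int]
#: type alias -- unordered degree pair (a <= b) -> number of edges in the class
EdgePartition = dict[tuple[int, int], int]


def _check_grid(m: int, n: int) -> None:
    """Reject anything that is not a pair of integers >= 1."""
    for name, v in (("m", m), ("n", n)):
        if isinstance(v, bool) or not isinstance(v, (int,)):
            raise TypeError(f"{name} must be an integer >= 1, got {v!r}")
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")


def ben4_counts(m: int, n: int) -> tuple[int, int]:
    """Vertex and edge count of the BeN4(m, n) molecular graph.

    Returns ``(5mn + m + n + 1, 8mn - n)``.
    """
    _check_grid(m, n)
    return 5 * m * n + m + n + 1, 8 * m * n - n


def ben4_vertex_partition(m: int, n: int) -> VertexPartition:
    """Vertex partition of BeN4(m, n): degree -> vertex count.

    The sheet contains vertices of degree 1 (the four corner pendants),
    degree 2 (boundary), degree 3 (bulk nitrogen) and degree 4 (bulk
    beryllium).  Counts sum to ``5mn + m + n + 1`` for all m, n >= 1.
    """
    _check_grid(m, n)
    return {
        1: 4,
        2: 2 * m + 4 * n - 4,
        3: 4 * m * n - 2 * n,
        4: m * n - m - n + 1,
    }


def ben4_edge_partition(
    m: int,
    n: int,
    freq33: int | Callable[[int, int], int] | None = None,
) -> EdgePartition:
    """Edge partition of BeN4(m, n): unordered degree pair -> edge count.

    Parameters
    ----------
    m, n
        Unit-cell counts along the two lattice directions, >= 1.
    freq33
        Optional override for the (3, 3)-class count.  The tabulated
        count is ``4mn - 3n`` (the default); several reference entropy
        tables are only reproducible with ``4mn - 4n`` instead (see
        :func:`ben4topo.entropy.reconciled_freq33`).  Accepts a plain
        count or a callable ``(m, n) -> count``.

    Counts sum to ``8mn - n`` for all m, n >= 1 under the default.
    """
    _check_grid(m, n)
    if freq33 is None:
        t33 = 4 * m * n - 3 * n
    elif callable(freq33):
        t33 = freq33(m, n)
    else:
        t33 = freq33
    if t33 < 0:
        raise ValueError(f"(3,3)-class count must be >= 0, got {t33}")
    return {
        (1, 2): 2,
        (1, 3): 2,
        (2, 2): 2 * n - 2,
        (2, 3): 4 * m + 4 * n - 6,
        (3, 3): t33,
        (3, 4): 4 * m * n - 4 * m - 4 * n + 4,
    }


def partitions_from_graph(g: nx.Graph) -> tuple[VertexPartition, EdgePartition]:
    """Tally the degree-level summaries of an arbitrary simple graph.

    Parameters
    ----------
    g
        Undirected simple graph.  Self-loops are rejected; ``nx.Graph``
        cannot represent duplicate edges.

    Returns
    -------
    (vertex_partition, edge_partition)
        Degree tallies and unordered endpoint-degree-pair tallies.
        Totals equal ``|V|`` and ``|E|``.
    """
    if g.is_directed() or g.is_multigraph():
        raise TypeError("expected an undirected simple graph (nx.Graph)")
    if any(u == v for u, v in nx.selfloop_edges(g)):
        raise ValueError("graph has self-loops; only simple graphs are supported")
    deg = dict(g.degree())
    vp: VertexPartition = {}
    for d in deg.values():
        vp[d] = vp.get(d, 0) + 1
    ep: EdgePartition = {}
    for u, v in g.edges():
        pair = (deg[u], deg[v]) if deg[u] <= deg[v] else (deg[v], deg[u])
        ep[pair] = ep.get(pair, 0) + 1
    return vp, ep


@dataclass
class ValidationReport:
    """Outcome of the partition consistency audit (report-only)."""

    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def __bool__(self) -> bool:  # truthiness == all checks pass
        return self.passed


def validate_partitions(vp: VertexPartition, ep: EdgePartition) -> ValidationReport:
    """Audit a vertex/edge partition pair for mutual consistency.

    Three checks, each flagged pass/fail, none raising:

    * ``non_negative`` -- every count >= 0;
    * ``handshake`` -- sum of d * vp[d] equals twice the edge total;
    * ``second_moment`` -- sum over edge classes of count * (a + b)
      equals sum of d^2 * vp[d].  Both sides tally degree sums over edge
      endpoints, so a consistent pair must agree.
    """
    report = ValidationReport()
    nonneg = all(c >= 0 for c in vp.values()) and all(c >= 0 for c in ep.values())
    report.checks["non_negative"] = nonneg

    degree_sum = sum(d * c for d, c in vp.items())
    edge_total = sum(ep.values())
    report.checks["handshake"] = degree_sum == 2 * edge_total
    report.details["handshake"] = f"sum(d*V_d)={degree_sum}, 2|E|={2 * edge_total}"

    lhs = sum(c * (a + b) for (a, b), c in ep.items())
    rhs = sum(d * d * c for d, c in vp.items())
    report.checks["second_moment"] = lhs == rhs
    report.details["second_moment"] = f"sum(Theta*(a+b))={lhs}, sum(d^2*V_d)={rhs}"
    return report


def read_edge_list(path) -> nx.Graph:
    """Read a simple graph from a plain-text edge list.

    One edge per line: two whitespace-separated positive integer vertex
    identifiers (1-based).  Lines starting with ``#`` and blank lines
    are ignored.  Self-loops and duplicate undirected edges are
    rejected.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two vertex ids, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer vertex id in {line!r}") from exc
            if u < 1 or v < 1:
                raise ValueError(f"{path}:{lineno}: vertex ids must be >= 1")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} not allowed")
            if g.has_edge(u, v):
                raise ValueError(f"{path}:{lineno}: duplicate edge {u}-{v}")
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a simple graph in the edge-list format of :func:`read_edge_list`.

    The format requires positive integer vertex ids; graphs labelled
    otherwise (e.g. 0-based generators) are relabelled 1..n in sorted
    node order, which leaves every degree-based quantity unchanged.
    """
    nodes = list(g.nodes())
    if not all(isinstance(v, int) and v >= 1 for v in nodes):
        g = nx.relabel_nodes(g, {v: i for i, v in enumerate(sorted(nodes), start=1)})
    with open(path, "w") as fh:
        fh.write(f"# {g.number_of_nodes()} vertices, {g.number_of_edges()} edges\n")
        for u, v in sorted(tuple(sorted((u, v))) for u, v in g.edges()):
            fh.write(f"{u} {v}\n")


def partition_frame(partition: VertexPartition | EdgePartition) -> pd.DataFrame:
    """Partition as a two-column DataFrame ``(class, count)``, CSV-ready."""
    rows = [
        {"class": k if isinstance(k, int) else f"({k[0]},{k[1]})", "count": c}
        for k, c in sorted(partition.items(), key=lambda kv: (0, kv[0], 0) if isinstance(kv[0], int) else (1,) + kv[0])
    ]
    return pd.DataFrame(rows, columns=["class", "count"])
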