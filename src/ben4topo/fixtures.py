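"""Synthetic graphs and regression data with known ground truth.

Everything downstream is testable without external input: classic
graphs (path, cycle, star, complete) have closed-form index values;
seeded random graphs drive oracle-equivalence checks of the partition
shortcut against a direct edge-by-edge sum; and synthetic (x, y) data
generated from ``y = beta0 + beta1*ln(x) + eps`` with Gaussian noise
exercises the regression stage with known coefficients.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .indices import edge_weight

__all__ = ["make_graph", "brute_force_index", "synthetic_log_data", "synthetic_power_data"]

_KINDS = ("path", "cycle", "star", "complete", "random")


def make_graph(
    kind: str,
    size: int,
    edge_probability: float = 0.3,
    seed: int | None = None,
) -> nx.Graph:
    """Build a classic or seeded-random simple graph.

    ``size`` is the vertex count (for ``star``: the number of leaves,
    matching the usual "star with k leaves" phrasing).  Random graphs
    are Erdos-Renyi G(n, p), reproducible per seed; isolated vertices
    may occur and are kept (they carry no edges, so degree-based indices
    ignore them).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    minimum = 3 if kind == "cycle" else 2
    if size < minimum:
        raise ValueError(f"{kind} graph needs size >= {minimum}, got {size}")
    if kind == "path":
        return nx.path_graph(size)
    if kind == "cycle":
        return nx.cycle_graph(size)
    if kind == "star":
        return nx.star_graph(size)  # hub + `size` leaves
    if kind == "complete":
        return nx.complete_graph(size)
    if not 0 < edge_probability <= 1:
        raise ValueError(f"edge_probability must be in (0, 1], got {edge_probability}")
    if seed is None:
        raise ValueError("random graphs require an explicit seed")
    return nx.gnp_random_graph(size, edge_probability, seed=seed)


def brute_force_index(g: nx.Graph, name: str) -> float:
    """Direct edge-by-edge index sum -- the oracle, no partition shortcut."""
    deg = dict(g.degree())
    return float(sum(edge_weight(name, deg[u], deg[v]) for u, v in g.edges()))


def synthetic_log_data(
    beta0: float, beta1: float, sigma: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) from ``y = beta0 + beta1*ln(x) + eps``, eps ~ N(0, sigma^2).

    x is a strictly increasing positive sequence (1..n); output is
    reproducible per seed.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    x = np.arange(1.0, n + 1.0)
    y = beta0 + beta1 * np.log(x) + rng.normal(0.0, sigma, size=n)
    return x, y


def synthetic_power_data(
    a: float, b: float, sigma: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) from ``y = a * x**b * exp(eps)``, eps ~ N(0, sigma^2).

    Multiplicative log-normal noise, the error structure under which the
    log-log OLS power fit is the natural estimator.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if a <= 0:
        raise ValueError(f"a must be > 0, got {a}")
    rng = np.random.default_rng(seed)
    x = np.arange(1.0, n + 1.0)
    y = a * x**b * np.exp(rng.normal(0.0, sigma, size=n))
    return x, y
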