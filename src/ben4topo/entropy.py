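"""Index-weighted Shannon entropies of the edge-weight distribution.

For a topological index ``TI = sum over edges of f(edge)`` with positive
edge weights ``f``, the weights induce a probability distribution
``p(edge) = f(edge) / W`` with ``W = TI``.  Its Shannon entropy (natural
logarithm throughout) is

    ENT = ln(W) - (1/W) * sum over edges of f * ln(f),

computed here per edge class as ``sum of count * f * ln(f)``.  The
entropy is maximal, ``ln |E|``, exactly when all edge weights are equal
(every regular graph); classes with weight 1 contribute nothing to the
sum.

Two normalizer conventions are supported for BeN4, mirroring the two
index modes:

* ``canonical`` -- W is the partition-times-weight sum (self-consistent
  Shannon entropy, guaranteed <= ln |E|);
* ``published`` -- W is the published closed-form polynomial (the
  convention the reference entropy tabulations follow; the bound may be
  violated marginally because W is not the true weight total).

The reference entropy tables are reproducible under the published-mode
normalizer only when the (3,3) edge-class count is taken as ``4mn - 4n``
(:func:`reconciled_freq33`) instead of the tabulated ``4mn - 3n`` -- for
every index except GA, whose (3,3) weight is exactly 1 so its entropy
row is insensitive to that count.  The tabulated count remains the
default everywhere; the override is opt-in.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import pandas as pd

from .indices import compute_index, edge_weight, published_value
from .structure import EdgePartition, ben4_edge_partition

__all__ = [
    "weighted_entropy",
    "index_entropy",
    "ben4_entropy",
    "entropy_series",
    "reconciled_freq33",
    "DIAGONAL_GRID",
]

#: the tabulated evaluation grid: (i, i) for i = 1..10
DIAGONAL_GRID: tuple[tuple[int, int], ...] = tuple((i, i) for i in range(1, 11))


def reconciled_freq33(m: int, n: int) -> int:
    """(3,3)-class count that reconciles the published tabulations.

    Empirical finding, not a tabulated fact: the published closed-form
    polynomials and the reference entropy tables are mutually consistent
    with a (3,3) count of ``4mn - 4n = 4n(m - 1)``, one ``n`` short of
    the tabulated ``4mn - 3n``.  Pass this as ``freq33`` to reproduce
    the non-GA reference entropy rows.
    """
    return 4 * m * n - 4 * n


def weighted_entropy(
    weights: Sequence[float], counts: Sequence[float], W: float | None = None
) -> float:
    """Shannon entropy of an edge-weight distribution given per class.

    ``weights[i]`` is the (positive) weight of each edge in class ``i``,
    ``counts[i]`` the number of such edges.  ``W`` defaults to the true
    weight total ``sum(count * weight)``; passing another positive value
    evaluates the same expression under that normalizer.
    """
    if len(weights) != len(counts):
        raise ValueError("weights and counts must have equal length")
    if any(w <= 0 for w, c in zip(weights, counts) if c):
        raise ValueError("all edge weights on non-empty classes must be > 0")
    if W is None:
        W = sum(c * w for w, c in zip(weights, counts))
    if W <= 0:
        raise ValueError(f"normalizer W must be > 0, got {W}")
    inner = sum(c * w * math.log(w) for w, c in zip(weights, counts) if c)
    return math.log(W) - inner / W


def index_entropy(ep: EdgePartition, name: str, W: float) -> float:
    """Entropy of the ``name``-index weight distribution on a partition.

    ``value = ln(W) - (1/W) * sum of count * w(a,b) * ln w(a,b)`` over
    the partition's non-empty classes.
    """
    pairs = [(a, b) for (a, b), c in ep.items() if c]
    weights = [edge_weight(name, a, b) for a, b in pairs]
    counts = [ep[p] for p in pairs]
    return weighted_entropy(weights, counts, W)


def _freq33_arg(freq33, m: int, n: int):
    return freq33(m, n) if callable(freq33) else freq33


def ben4_entropy(
    name: str,
    m: int,
    n: int,
    mode: str = "published",
    freq33: int | Callable[[int, int], int] | None = None,
) -> float:
    """Index entropy of BeN4(m, n) in one of the two normalizer modes.

    ``mode="published"`` uses the published polynomial as W;
    ``mode="canonical"`` uses the partition-times-weight sum (which then
    respects the ``<= ln |E|`` bound).  ``freq33`` overrides the (3,3)
    edge-class count in *both* the weight sum and, in canonical mode,
    the normalizer.
    """
    ep = ben4_edge_partition(m, n, freq33=_freq33_arg(freq33, m, n) if freq33 is not None else None)
    if mode == "published":
        W = published_value(name, m, n)
    elif mode == "canonical":
        W = compute_index(ep, name)
    else:
        raise ValueError(f"mode must be 'canonical' or 'published', got {mode!r}")
    return index_entropy(ep, name, W)


def entropy_series(
    name: str,
    grid: Iterable[tuple[int, int]] = DIAGONAL_GRID,
    mode: str = "published",
    freq33: int | Callable[[int, int], int] | None = None,
) -> pd.Series:
    """Entropy of one index over a grid of (m, n) points.

    Returns a Series indexed by the (m, n) tuples, in grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    values = [ben4_entropy(name, m, n, mode=mode, freq33=freq33) for m, n in grid]
    return pd.Series(values, index=pd.Index(grid, tupleize_cols=False), name=name)
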