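"""Degree-based topological indices: canonical sums and published closed forms.

Every index here has the form ``TI(G) = sum over edges uv of w(d_u, d_v)``
with ``w`` a symmetric weight in the endpoint degrees, so it is computed
exactly from an edge partition ("canonical" mode).  For the BeN4(m, n)
sheet, closed-form polynomials ``c_mn*mn + c_m*m + c_n*n + c_0`` have
also been published for all 14 indices ("published" mode).

The two modes disagree for BeN4: the published polynomials are not the
partition-times-weight sums of the tabulated edge partition (their
n-coefficients are systematically off, consistent with a (3,3)-class
count of ``4mn - 4n`` rather than the tabulated ``4mn - 3n``).  Neither
mode is silently preferred; :func:`discrepancy` quantifies the gap and
:func:`reconciling_freq33` solves for the (3,3) count each published
polynomial implies.

Index registry (``a``, ``b`` are the endpoint degrees):

========  =====================================
name      weight w(a, b)
========  =====================================
R1        a*b                (Randic, alpha=1)
R-1       1/(a*b)            (alpha=-1)
R1/2      sqrt(a*b)          (alpha=1/2)
R-1/2     1/sqrt(a*b)        (alpha=-1/2)
ABC       sqrt((a+b-2)/(a*b))
GA        2*sqrt(a*b)/(a+b)
M1        a + b              (first Zagreb)
M2        a * b              (second Zagreb)
HM        (a+b)**2           (hyper Zagreb)
F         a**2 + b**2        (forgotten)
AZI       ((a*b)/(a+b-2))**3 (augmented Zagreb)
ReZG1     (a+b)/(a*b)        (redefined Zagreb)
ReZG2     (a*b)/(a+b)
ReZG3     (a*b)*(a+b)
========  =====================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .structure import EdgePartition, ben4_edge_partition, _check_grid

__all__ = [
    "INDEX_NAMES",
    "RANDIC_ALPHA",
    "PUBLISHED_POLYNOMIALS",
    "edge_weight",
    "randic_weight",
    "compute_index",
    "published_value",
    "discrepancy",
    "Discrepancy",
    "reconciling_freq33",
]

#: the 14 indices, in tabulation order
INDEX_NAMES: tuple[str, ...] = (
    "R1", "R-1", "R1/2", "R-1/2",
    "ABC", "GA", "M1", "M2",
    "HM", "F", "AZI", "ReZG1", "ReZG2", "ReZG3",
)

#: Randic exponent per registered Randic-family name
RANDIC_ALPHA: dict[str, float] = {"R1": 1.0, "R-1": -1.0, "R1/2": 0.5, "R-1/2": -0.5}

#: published closed-form coefficients (c_mn, c_m, c_n, c_0) of
#: value = c_mn*mn + c_m*m + c_n*n + c_0, transcribed verbatim from the
#: reference derivations -- including their internal inconsistencies.
PUBLISHED_POLYNOMIALS: dict[str, tuple[float, float, float, float]] = {
    "R1":    (84.0, -24.0, -52.0, 14.0),
    "R-1":   (0.7778, 0.3333, 0.3889, 0.5),
    "R1/2":  (25.8564, -4.0584, -12.0584, 1.4519),
    "R-1/2": (2.4880, 0.4783, 0.1449, 0.2741),
    "ABC":   (5.2486, 0.2464, -1.0060, -0.0276),
    "GA":    (7.9589, -0.0793, -2.0397, -0.3021),
    "M1":    (52.0, -8.0, -24.0, 4.0),
    "M2":    (84.0, -24.0, -52.0, 14.0),
    "HM":    (340.0, -96.0, -208.0, 64.0),
    "F":     (172.0, -48.0, -104.0, 36.0),
    "AZI":   (100.8585, -23.2960, -52.8585, 14.0460),
    "ReZG1": (5.0, 1.0, 0.3333, 1.0),
    "ReZG2": (12.8571, -2.0571, -6.0571, 0.4905),
    "ReZG3": (544.0, -208.0, -392.0, 152.0),
}


def randic_weight(a: int, b: int, alpha: float) -> float:
    """Randic edge weight ``(a*b)**alpha`` for any real exponent."""
    _check_degrees(a, b)
    return float(a * b) ** alpha


def _check_degrees(a: int, b: int) -> None:
    if a < 1 or b < 1:
        raise ValueError(f"degrees must be >= 1, got ({a}, {b})")


def edge_weight(name: str, a: int, b: int) -> float:
    """Weight contributed by an edge with endpoint degrees ``a``, ``b``.

    ABC and AZI divide by ``a + b - 2`` (under a square root / cubed),
    so a pendant-pendant edge (a = b = 1) is rejected for those two.
    """
    _check_degrees(a, b)
    if name in RANDIC_ALPHA:
        return float(a * b) ** RANDIC_ALPHA[name]
    if name == "ABC":
        if a + b <= 2:
            raise ValueError("ABC weight undefined for a degree-1/degree-1 edge")
        return math.sqrt((a + b - 2) / (a * b))
    if name == "GA":
        return 2.0 * math.sqrt(a * b) / (a + b)
    if name == "M1":
        return float(a + b)
    if name == "M2":
        return float(a * b)
    if name == "HM":
        return float((a + b) ** 2)
    if name == "F":
        return float(a * a + b * b)
    if name == "AZI":
        if a + b <= 2:
            raise ValueError("AZI weight undefined for a degree-1/degree-1 edge")
        return ((a * b) / (a + b - 2)) ** 3
    if name == "ReZG1":
        return (a + b) / (a * b)
    if name == "ReZG2":
        return (a * b) / (a + b)
    if name == "ReZG3":
        return float((a * b) * (a + b))
    raise KeyError(f"unknown index {name!r}; known: {', '.join(INDEX_NAMES)}")


def compute_index(ep: EdgePartition, name: str) -> float:
    """Canonical index value: sum over edge classes of count * weight.

    Empty classes (count 0) are skipped, so e.g. ABC is computable on a
    partition that lists a (1,1) class with zero edges.
    """
    return float(sum(c * edge_weight(name, a, b) for (a, b), c in ep.items() if c))


def published_value(name: str, m: int, n: int) -> float:
    """Evaluate the published closed-form polynomial for BeN4(m, n).

    The coefficients are transcribed verbatim, including the internal
    inconsistencies with the tabulated edge partition; see
    :func:`discrepancy`.
    """
    _check_grid(m, n)
    try:
        c_mn, c_m, c_n, c_0 = PUBLISHED_POLYNOMIALS[name]
    except KeyError:
        raise KeyError(f"unknown index {name!r}; known: {', '.join(INDEX_NAMES)}") from None
    return c_mn * m * n + c_m * m + c_n * n + c_0


@dataclass(frozen=True)
class Discrepancy:
    """Canonical-vs-published gap for one index at one grid point."""

    name: str
    m: int
    n: int
    canonical: float
    published: float

    @property
    def difference(self) -> float:
        return self.canonical - self.published


def discrepancy(name: str, m: int, n: int) -> Discrepancy:
    """Canonical (tabulated partition x weights) vs published polynomial.

    The two provably differ for BeN4 (e.g. canonical M1 at (1,1) is 30,
    published 24).  This function quantifies, and does not adjudicate,
    that gap.
    """
    canon = compute_index(ben4_edge_partition(m, n), name)
    return Discrepancy(name, m, n, canon, published_value(name, m, n))


def reconciling_freq33(name: str, m: int, n: int) -> float:
    """(3,3)-class count implied by the published polynomial.

    Solves ``count = (published - sum over other classes) / w(3, 3)``.
    For every index whose published coefficients are exact integers --
    except ReZG3 -- this returns exactly ``4mn - 4n``, one ``n`` short of
    the tabulated ``4mn - 3n``; the 4-decimal polynomials agree to ~1e-3.
    ReZG3's polynomial is inconsistent with any single (3,3) count.
    """
    ep = ben4_edge_partition(m, n, freq33=0)
    rest = compute_index(ep, name)
    return (published_value(name, m, n) - rest) / edge_weight(name, 3, 3)
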