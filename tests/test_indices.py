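"""Canonical index sums, published polynomials, and the gap between them."""

import math

import pytest

from ben4topo import (
    INDEX_NAMES,
    ben4_edge_partition,
    ben4_vertex_partition,
    compute_index,
    discrepancy,
    edge_weight,
    published_value,
    randic_weight,
    reconciling_freq33,
)


@pytest.mark.parametrize(
    "name, a, b, expected",
    [
        ("GA", 3, 3, 1.0),
        ("ABC", 2, 3, math.sqrt(3 / 6)),
        ("AZI", 3, 3, (9 / 4) ** 3),
        ("M1", 2, 3, 5.0),
        ("M2", 2, 3, 6.0),
        ("HM", 3, 4, 49.0),
        ("F", 1, 4, 17.0),
        ("ReZG1", 3, 4, 7 / 12),
        ("ReZG2", 3, 4, 12 / 7),
        ("ReZG3", 3, 4, 84.0),
        ("R1", 3, 4, 12.0),
        ("R-1", 3, 4, 1 / 12),
        ("R1/2", 3, 4, math.sqrt(12)),
        ("R-1/2", 3, 4, 1 / math.sqrt(12)),
    ],
)
def test_edge_weight_registry(name, a, b, expected):
    assert edge_weight(name, a, b) == pytest.approx(expected, abs=1e-12)
    assert edge_weight(name, b, a) == pytest.approx(expected, abs=1e-12)  # symmetry


def test_randic_weight_accepts_any_alpha():
    assert randic_weight(2, 3, 0.25) == pytest.approx(6**0.25)


@pytest.mark.parametrize("name", ["ABC", "AZI"])
def test_degenerate_pendant_pendant_edge_rejected(name):
    with pytest.raises(ValueError):
        edge_weight(name, 1, 1)


def test_unknown_index_rejected():
    with pytest.raises(KeyError):
        edge_weight("Wiener", 2, 3)
    with pytest.raises(KeyError):
        published_value("Wiener", 1, 1)


def test_canonical_m1_unit_cell_brute_force(unit_cell_partitions):
    # oracle: the seven edges of the m=n=1 sheet, summed degree pairs
    # 2x(1+2) + 2x(1+3) + 2x(2+3) + 1x(3+3) = 6 + 8 + 10 + 6 = 30
    _, ep = unit_cell_partitions
    assert compute_index(ep, "M1") == 30.0


def test_canonical_on_regular_partition():
    # complete graph on 4 vertices: 6 edges, all degree pairs (3,3)
    ep = {(3, 3): 6}
    assert compute_index(ep, "GA") == 6.0
    assert compute_index(ep, "ReZG2") == 6 * 3 / 2
    for alpha, name in ((1, "R1"), (-1, "R-1"), (0.5, "R1/2"), (-0.5, "R-1/2")):
        assert compute_index(ep, name) == pytest.approx(6 * 3.0 ** (2 * alpha))


def test_r1_equals_m2_on_any_partition():
    for m, n in [(1, 1), (2, 5), (7, 3), (10, 10)]:
        ep = ben4_edge_partition(m, n)
        assert compute_index(ep, "R1") == compute_index(ep, "M2")


def test_canonical_m1_is_degree_second_moment():
    for m in range(1, 21):
        for n in range(1, 21):
            vp = ben4_vertex_partition(m, n)
            ep = ben4_edge_partition(m, n)
            assert compute_index(ep, "M1") == sum(d * d * c for d, c in vp.items())


@pytest.mark.parametrize(
    "name, m, n, expected",
    [
        ("R1", 1, 1, 22.0),
        ("M1", 10, 10, 4884.0),
        ("HM", 1, 1, 100.0),
        ("ReZG3", 10, 10, 48552.0),
        ("M2", 10, 10, 7654.0),
        ("F", 5, 5, 3576.0),
    ],
)
def test_published_polynomial_values(name, m, n, expected):
    assert published_value(name, m, n) == pytest.approx(expected)


def test_published_r1_identical_to_m2():
    for m, n in [(1, 1), (4, 9), (10, 10)]:
        assert published_value("R1", m, n) == published_value("M2", m, n)


@pytest.mark.parametrize(
    "name, canonical, published",
    [("M1", 30.0, 24.0), ("HM", 136.0, 100.0)],
)
def test_discrepancy_unit_cell(name, canonical, published):
    d = discrepancy(name, 1, 1)
    assert d.canonical == pytest.approx(canonical)
    assert d.published == pytest.approx(published)
    assert d.difference == pytest.approx(canonical - published)


def test_canonical_strictly_increasing_in_m_and_n():
    for name in INDEX_NAMES:
        for m, n in [(1, 1), (3, 2), (5, 5)]:
            base = compute_index(ben4_edge_partition(m, n), name)
            assert compute_index(ben4_edge_partition(m + 1, n), name) > base
            assert compute_index(ben4_edge_partition(m, n + 1), name) > base


def test_reconciling_freq33_is_4mn_minus_4n_for_exact_polynomials():
    # for indices with exactly-printed integer coefficients the (3,3)
    # count implied by the published polynomial is 4mn - 4n on the nose
    for name in ("R1", "M1", "M2", "HM", "F"):
        for m, n in [(1, 1), (2, 3), (5, 5), (7, 4)]:
            assert reconciling_freq33(name, m, n) == pytest.approx(4 * m * n - 4 * n, abs=1e-9)
    # 4-decimal polynomials agree to rounding error
    for name in ("AZI", "ABC", "GA", "ReZG1", "ReZG2"):
        for m, n in [(2, 3), (5, 5)]:
            assert reconciling_freq33(name, m, n) == pytest.approx(4 * m * n - 4 * n, abs=0.35)


def test_rezg3_polynomial_reconciles_with_no_single_count():
    # ReZG3's published polynomial is off by 8(m-1)(n-1) even after the
    # (3,3) reconciliation -- its implied count is not 4mn - 4n
    assert abs(reconciling_freq33("ReZG3", 5, 5) - 80) > 1
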