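"""Agreement statistics: table reconstruction, kappa, Brennan-Prediger."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungpanel.concordance import (
    ContingencyTable,
    brennan_prediger,
    classify_strength,
    cohen_kappa,
    raw_agreement,
    reconstruct_table,
)
from lungpanel.errors import DegenerateStatisticsError, ValidationError


def all_tables(max_n: int):
    """Enumerate every 2x2 table with 1 <= n <= max_n."""
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield ContingencyTable(a=a, b=b, c=c, d=n - a - b - c)


@pytest.mark.parametrize(
    "marginals, cells",
    [
        ((497, 294, 262, 413), (236, 26, 58, 177)),
        ((95, 80, 82, 87), (77, 5, 3, 10)),
        ((10, 5, 5, 10), (5, 0, 0, 5)),
    ],
)
def test_reconstruct_table(marginals, cells):
    t = reconstruct_table(*marginals)
    assert (t.a, t.b, t.c, t.d) == cells
    assert (t.n, t.reference_positive, t.index_positive, t.agreement) == marginals


@pytest.mark.parametrize(
    "marginals",
    [
        (10, 5, 5, 9),   # parity violation: no integer cell solution
        (10, 9, 9, 0),   # negative cell
        (10, 11, 5, 5),  # marginal exceeds n
    ],
)
def test_reconstruct_inconsistent_marginals(marginals):
    with pytest.raises(ValidationError):
        reconstruct_table(*marginals)


@pytest.mark.parametrize(
    "cells, want",
    [
        ((236, 26, 58, 177), 413 / 497),
        ((77, 5, 3, 10), 87 / 95),
        ((0, 4, 4, 0), 0.0),
    ],
)
def test_raw_agreement(cells, want):
    assert raw_agreement(ContingencyTable(*cells)) == pytest.approx(want)


def test_kappa_published_values():
    k = cohen_kappa(ContingencyTable(236, 26, 58, 177))
    assert round(k.kappa, 3) == 0.659
    assert tuple(round(x, 3) for x in k.ci) == (0.592, 0.725)
    kp = cohen_kappa(ContingencyTable(77, 5, 3, 10))
    assert round(kp.kappa, 3) == 0.665


def test_kappa_perfect_diagonal():
    assert cohen_kappa(ContingencyTable(10, 0, 0, 10)).kappa == pytest.approx(1.0)


def test_kappa_degenerate_margins():
    with pytest.raises(DegenerateStatisticsError):
        cohen_kappa(ContingencyTable(5, 0, 0, 0))


def test_brennan_prediger_published_values():
    b = brennan_prediger(ContingencyTable(236, 26, 58, 177))
    assert round(b.bp, 3) == 0.662
    assert tuple(round(x, 3) for x in b.ci) == (0.596, 0.728)
    bp = brennan_prediger(ContingencyTable(77, 5, 3, 10))
    assert round(bp.bp, 3) == 0.832
    assert brennan_prediger(ContingencyTable(1, 1, 1, 1)).bp == pytest.approx(0.0)


@pytest.mark.parametrize(
    "value, want",
    [
        (0.659, "substantial"),
        (0.832, "almost perfect"),
        (-0.2, "poor"),
        (0.0, "poor"),
        (0.1, "slight"),
        (0.3, "fair"),
        (0.5, "moderate"),
        (1.0, "almost perfect"),
    ],
)
def test_strength_bins(value, want):
    assert classify_strength(value) == want


def test_strength_out_of_range():
    with pytest.raises(ValidationError):
        classify_strength(1.2)


def test_brute_force_oracle_small_tables():
    """kappa and BP match a from-definition recomputation on every 2x2
    table with n <= 12, along with transpose symmetry and the q=2
    Brennan-Prediger identity bp = 2*po - 1."""
    for t in all_tables(12):
        po = (t.a + t.d) / t.n
        bp = brennan_prediger(t)
        assert bp.bp == pytest.approx(2 * po - 1, abs=1e-12)
        p_row = [(t.a + t.c) / t.n, (t.b + t.d) / t.n]
        p_col = [(t.a + t.b) / t.n, (t.c + t.d) / t.n]
        pe = p_row[0] * p_col[0] + p_row[1] * p_col[1]
        if pe < 1:
            k = cohen_kappa(t)
            assert k.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
            kt = cohen_kappa(t.transpose())
            assert kt.kappa == pytest.approx(k.kappa, abs=1e-12)
            # kappa = 1 and po = 1 exactly when there is no disagreement
            assert (k.kappa == pytest.approx(1.0)) == (t.b == t.c == 0)
            assert (po == 1.0) == (t.b == t.c == 0)


def test_kappa_against_sklearn():
    """Independent route: expand the table into label vectors and compare
    with scikit-learn's Cohen's kappa."""
    from sklearn.metrics import cohen_kappa_score

    for cells in [(236, 26, 58, 177), (77, 5, 3, 10), (8, 3, 1, 5)]:
        t = ContingencyTable(*cells)
        ref = [1] * (t.a + t.c) + [0] * (t.b + t.d)
        idx = [1] * t.a + [0] * t.c + [1] * t.b + [0] * t.d
        assert cohen_kappa(t).kappa == pytest.approx(
            cohen_kappa_score(ref, idx), abs=1e-12
        )


@settings(max_examples=300, deadline=None)
@given(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
)
def test_reconstruct_round_trip(a, b, c, d):
    """Marginals of any table reconstruct to that table."""
    if a + b + c + d == 0:
        return
    t = ContingencyTable(a, b, c, d)
    t2 = reconstruct_table(t.n, t.reference_positive, t.index_positive, t.agreement)
    assert t2 == t


def test_ci_clamped_to_unit_interval():
    k = cohen_kappa(ContingencyTable(10, 1, 1, 10))
    assert -1 <= k.ci[0] <= k.kappa <= k.ci[1] <= 1
    b = brennan_prediger(ContingencyTable(1, 0, 0, 1))
    assert b.ci == (pytest.approx(1.0), pytest.approx(1.0))
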