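"""Separation-factor aggregation, the abridged life table, and e0."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stmflife import (STMF_SCHEME, AgeGroupScheme, LifeExpectancyResult,
                      SeparationFactors, aggregate_separation_factors,
                      build_abridged_lifetable, e0_drop, group_rates,
                      life_expectancy_at_birth, mx_to_qx)
from stmflife.lifetable import DropRecord
from stmflife.stmf_io import SingleAgeLifeTable


def _table_from_l(l: np.ndarray) -> SingleAgeLifeTable:
    """Single-age table with trapezoidal person-years from a survival curve."""
    l = np.asarray(l, float)
    d = np.append(l[:-1] - l[1:], l[-1])
    L = np.append((l[:-1] + l[1:]) / 2.0, l[-1] / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(l > 0, d / l, 1.0)
        m = np.where(L > 0, d / L, 0.0)
        a = np.where(d > 0, (L - np.append(l[1:], 0.0)) / np.where(d > 0, d, 1), 0.5)
    T = L[::-1].cumsum()[::-1]
    e = np.where(l > 0, T / np.where(l > 0, l, 1), 0.0)
    df = pd.DataFrame({"mx": m, "qx": np.minimum(q, 1), "ax": a, "lx": l,
                       "dx": d, "Lx": L, "Tx": T, "ex": e},
                      index=pd.Index(np.arange(len(l)), name="Age"))
    return SingleAgeLifeTable(data=df)


def test_linear_survival_gives_midpoint_nax():
    """With l declining linearly and trapezoidal L, those dying in a group
    die on average halfway through it: nax = n/2."""
    l = np.linspace(100_000.0, 0.0, 111)          # linear to zero at 110
    table = _table_from_l(l)
    sep = aggregate_separation_factors(table, STMF_SCHEME)
    assert sep.nax["65-74"] == pytest.approx(5.0, abs=1e-9)
    assert sep.nax["0-14"] == pytest.approx(7.5, abs=1e-9)


def test_single_year_groups_recover_reference_ax(reference_table):
    table, _ = reference_table
    scheme = AgeGroupScheme(lower_bounds=tuple(range(0, 110)))
    sep = aggregate_separation_factors(table, scheme)
    for lab, lo, n in scheme.iter_groups():
        if n is None:
            continue
        assert sep.nax[lab] == pytest.approx(float(table.data["ax"].loc[lo]),
                                             abs=1e-9)


def test_deathless_group_falls_back_to_midpoint_with_warning():
    l = np.concatenate([np.linspace(100_000, 90_000, 66),
                        np.full(10, 90_000.0),       # nobody dies in 65-74
                        np.linspace(90_000, 0, 35)])
    table = _table_from_l(l)
    with pytest.warns(UserWarning, match="nax = n/2"):
        sep = aggregate_separation_factors(table, STMF_SCHEME)
    assert sep.nax["65-74"] == 5.0


def test_nax_strictly_inside_interval(reference_table):
    table, _ = reference_table
    sep = aggregate_separation_factors(table, STMF_SCHEME)
    for lab, _, n in STMF_SCHEME.iter_groups():
        if n is not None:
            assert 0 < sep.nax[lab] < n


@pytest.mark.parametrize("m, n, a, expected", [
    (0.0, 10, 5, 0.0),
    (2.0, 1, 0.5, 1.0),
    (0.02, 10, 5, 0.2 / 1.1),
])
def test_mx_to_qx_standard_conversion(m, n, a, expected):
    assert mx_to_qx(m, n, a) == pytest.approx(expected, rel=1e-12)


def test_mx_to_qx_rejects_negative_rate_and_caps_at_one():
    with pytest.raises(ValueError, match="nonnegative"):
        mx_to_qx(-0.1, 5, 2.5)
    with pytest.warns(UserWarning, match="capping"):
        assert mx_to_qx(10.0, 5, 0.5) == 1.0


def test_single_open_group_constant_hazard_e0_is_reciprocal_rate():
    scheme = AgeGroupScheme(lower_bounds=(0,))
    lt = build_abridged_lifetable({"0+": 0.02},
                                  SeparationFactors(scheme=scheme, nax={}))
    assert life_expectancy_at_birth(lt) == pytest.approx(50.0, abs=1e-9)


def test_everyone_dying_in_first_group_leaves_e0_equal_to_a():
    nax = {"0-14": 0.5, "15-64": 25.0, "65-74": 5.0, "75-84": 5.0}
    sep = SeparationFactors(scheme=STMF_SCHEME, nax=nax)
    m = {lab: 0.1 for lab in STMF_SCHEME.labels}
    m["0-14"] = 1e9                                  # q pinned to 1
    with pytest.warns(UserWarning, match="capping"):
        lt = build_abridged_lifetable(m, sep)
    assert lt.e0 == pytest.approx(0.5)
    assert lt.data["l"].iloc[1] == 0.0


def test_open_group_zero_rate_is_an_error():
    scheme = AgeGroupScheme(lower_bounds=(0,))
    with pytest.raises(ValueError, match="open"):
        build_abridged_lifetable({"0+": 0.0},
                                 SeparationFactors(scheme=scheme, nax={}))


def test_rates_and_nax_from_same_reference_reproduce_its_qx(reference_table):
    """The aggregation identity: with m = ndx/nLx and nax from the
    person-years formula, abridged q equals the reference interval q."""
    table, _ = reference_table
    sep = aggregate_separation_factors(table, STMF_SCHEME)
    lt = build_abridged_lifetable(group_rates(table, STMF_SCHEME), sep)
    lx = table.data["lx"]
    for lab, lo, n in STMF_SCHEME.iter_groups():
        if n is None:
            continue
        q_ref = 1.0 - float(lx.loc[lo + n] / lx.loc[lo])
        assert abs(lt.data["q"].loc[lab] - q_ref) <= 1e-12
    assert lt.e0 == pytest.approx(table.e0, abs=1e-9)


@pytest.mark.parametrize("k", [1.2, 2.0, 5.0])
def test_uniform_rate_increase_strictly_lowers_e0(reference_table, k):
    table, _ = reference_table
    sep = aggregate_separation_factors(table, STMF_SCHEME)
    m = group_rates(table, STMF_SCHEME)
    base = build_abridged_lifetable(m, sep).e0
    worse = build_abridged_lifetable({lab: k * v for lab, v in m.items()}, sep).e0
    assert worse < base


@pytest.mark.filterwarnings("ignore::UserWarning")   # q capping is expected
@settings(derandomize=True, max_examples=40)
@given(scale=st.floats(min_value=0.2, max_value=5.0))
def test_identities_hold_on_scaled_rate_tables(reference_table, scale):
    """Sum(d)=radix, T reverse-cumulative, e=T/l for arbitrary rate levels."""
    table, _ = reference_table
    sep = aggregate_separation_factors(table, STMF_SCHEME)
    m = {lab: scale * v for lab, v in group_rates(table, STMF_SCHEME).items()}
    lt = build_abridged_lifetable(m, sep)
    lt.validate(tol=1e-9)


# --- drop records ------------------------------------------------------------

def test_drop_is_zero_for_equal_years():
    a = LifeExpectancyResult("TST", "both", 2019, 80.0)
    b = LifeExpectancyResult("TST", "both", 2020, 80.0)
    assert e0_drop(a, b).difference == 0.0


def test_drop_is_antisymmetric():
    a = LifeExpectancyResult("TST", "both", 2019, 81.5)
    b = LifeExpectancyResult("TST", "both", 2020, 80.25)
    assert e0_drop(a, b).difference == -e0_drop(b, a).difference


def test_drop_rejects_mismatched_series():
    a = LifeExpectancyResult("AAA", "both", 2019, 80.0)
    b = LifeExpectancyResult("BBB", "both", 2020, 79.0)
    with pytest.raises(ValueError, match="mismatched"):
        e0_drop(a, b)


def test_difference_computed_before_rounding():
    """Printed columns may disagree with the printed difference by 0.01:
    the difference is taken on unrounded e0, then rounded for display."""
    rec = DropRecord("TST", "both", e0_prev=72.515, e0_curr=70.352)
    assert round(rec.e0_prev, 2) == 72.52 and round(rec.e0_curr, 2) == 70.35
    assert round(rec.difference, 2) == 2.16          # not 72.52 - 70.35 = 2.17
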