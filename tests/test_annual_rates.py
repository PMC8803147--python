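"""Annualization, trailing-week imputation and unknown-week adjustment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stmflife import (STMF_SCHEME, WeeklyRecord, WeeklySeries,
                      adjust_for_unassigned_deaths, annualize,
                      impute_missing_weeks, weekly_rate)
from stmflife.annual_rates import MissingWeeksError
from stmflife.stmf_io import ExposureSet

from conftest import make_uniform_series

E = 52_000.0


def _exposures(years, exposure=E, country="TST", sex="both"):
    exp = ExposureSet()
    for year in years:
        for lab in STMF_SCHEME.labels:
            exp.set(country, sex, year, lab, exposure)
    return exp


@pytest.mark.parametrize("deaths, exposure, expected", [
    (10, 52_000, 0.01),
    (0, 123.0, 0.0),
    (7, 364, 1.0),
])
def test_weekly_rate_annualizes_counts(deaths, exposure, expected):
    assert weekly_rate(deaths, exposure) == pytest.approx(expected)


def test_weekly_rate_rejects_nonpositive_exposure():
    with pytest.raises(ValueError, match="exposure"):
        weekly_rate(1, 0)


def test_annualize_sums_weekly_deaths_over_exposure():
    series = make_uniform_series({2020: {lab: 10 for lab in STMF_SCHEME.labels}})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    assert rates.m["15-64"] == pytest.approx(520 / E)
    assert rates.w_tilde == 0 and rates.n_observed_weeks == 52


def test_annualize_of_zero_deaths_is_zero():
    series = make_uniform_series({2020: {}})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    assert all(v == 0.0 for v in rates.m.values())


def test_annualize_is_mean_of_annualized_weekly_rates():
    # 26 weeks at annualized rate 0.01, 26 at 0.03 -> annual 0.02;
    # cross-checked by summing counts: rate r means r*E/52 deaths per week
    series = WeeklySeries(scheme=STMF_SCHEME)
    for w in range(1, 53):
        r = 0.01 if w <= 26 else 0.03
        d = {lab: r * E / 52 for lab in STMF_SCHEME.labels}
        series.add(WeeklyRecord("TST", "both", 2020, w, d,
                                {lab: r for lab in STMF_SCHEME.labels}))
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    assert rates.m["0-14"] == pytest.approx(0.02)
    total_deaths = sum(rec.deaths["0-14"] for rec in series.records)
    assert rates.m["0-14"] * E == pytest.approx(total_deaths)


def test_annualize_requires_all_52_weeks():
    series = make_uniform_series({2020: {"0-14": 1}}, weeks=range(1, 52))
    with pytest.raises(MissingWeeksError, match="impute"):
        annualize(series, "TST", "both", 2020, _exposures([2020]))


def test_week53_is_excluded_by_default_and_included_by_all_policy():
    series = make_uniform_series({2020: {lab: 10 for lab in STMF_SCHEME.labels}},
                                 weeks=range(1, 54))
    exp = _exposures([2020])
    iso = annualize(series, "TST", "both", 2020, exp, weeks="iso52")
    assert iso.m["0-14"] == pytest.approx(520 / E)
    all_w = annualize(series, "TST", "both", 2020, exp, weeks="all")
    # 53 uniform weeks over exposure scaled by 53/52: same rate
    assert all_w.m["0-14"] == pytest.approx(530 / (E * 53 / 52))


def test_imputation_with_no_missing_weeks_matches_annualize():
    series = make_uniform_series({2019: {"0-14": 7}, 2020: {"0-14": 9}})
    exp = _exposures([2019, 2020])
    direct = annualize(series, "TST", "both", 2020, exp)
    imputed = impute_missing_weeks(series, "TST", "both", 2020, 2019, exp)
    assert imputed.m == pytest.approx(direct.m, rel=1e-12)
    assert imputed.w_tilde == 0 and imputed.imputation_source_year is None


def test_imputation_fills_trailing_weeks_from_reference_rates():
    # 48 target weeks at annualized rate 0.03, reference at 0.02, w~=4
    series = WeeklySeries(scheme=STMF_SCHEME)
    for w in range(1, 53):
        d = {lab: 0.02 * E / 52 for lab in STMF_SCHEME.labels}
        series.add(WeeklyRecord("TST", "both", 2019, w, d,
                                {lab: 0.02 for lab in STMF_SCHEME.labels}))
    for w in range(1, 49):
        d = {lab: 0.03 * E / 52 for lab in STMF_SCHEME.labels}
        series.add(WeeklyRecord("TST", "both", 2020, w, d,
                                {lab: 0.03 for lab in STMF_SCHEME.labels}))
    rates = impute_missing_weeks(series, "TST", "both", 2020, 2019,
                                 _exposures([2019, 2020]))
    assert rates.m["65-74"] == pytest.approx((48 * 0.03 + 4 * 0.02) / 52)
    assert rates.w_tilde == 4
    assert rates.imputation_source_year == 2019


def test_imputing_a_fully_missing_year_returns_reference_rates():
    series = make_uniform_series({2019: {"85+": 20}})
    exp = _exposures([2019, 2020])
    rates = impute_missing_weeks(series, "TST", "both", 2020, 2019, exp)
    ref = annualize(series, "TST", "both", 2019, exp)
    assert rates.m == pytest.approx(ref.m)
    assert rates.w_tilde == 52


def test_internal_gaps_rejected_unless_allowed():
    weeks = [w for w in range(1, 53) if w != 30]
    series = make_uniform_series({2019: {"0-14": 5}})
    for w in weeks:
        d = {lab: 5.0 if lab == "0-14" else 0.0 for lab in STMF_SCHEME.labels}
        series.add(WeeklyRecord("TST", "both", 2020, w, d,
                                {lab: 52 * d[lab] / E for lab in STMF_SCHEME.labels}))
    exp = _exposures([2019, 2020])
    with pytest.raises(MissingWeeksError, match="trailing"):
        impute_missing_weeks(series, "TST", "both", 2020, 2019, exp)
    rates = impute_missing_weeks(series, "TST", "both", 2020, 2019, exp,
                                 allow_internal_gaps=True)
    assert rates.w_tilde == 1


def test_reference_year_with_missing_weeks_is_rejected():
    series = make_uniform_series({2019: {"0-14": 5}}, weeks=range(1, 50))
    with pytest.raises(MissingWeeksError, match="reference year"):
        impute_missing_weeks(series, "TST", "both", 2020, 2019,
                             _exposures([2019, 2020]))


@settings(derandomize=True, max_examples=25)
@given(w_tilde=st.integers(min_value=0, max_value=52))
def test_imputation_is_noop_when_target_equals_reference(w_tilde):
    """If target rates equal reference rates week-by-week, any amount of
    censoring leaves the annual rate unchanged."""
    per = {lab: 6.0 for lab in STMF_SCHEME.labels}
    full = make_uniform_series({2019: per, 2020: per})
    exp = _exposures([2019, 2020])
    want = annualize(full, "TST", "both", 2020, exp).m
    censored = make_uniform_series({2019: per})
    for w in range(1, 53 - w_tilde):
        rec = full.get("TST", "both", 2020, w)
        censored.add(rec)
    got = impute_missing_weeks(censored, "TST", "both", 2020, 2019, exp)
    assert got.m == pytest.approx(want, rel=1e-12)
    assert got.w_tilde == w_tilde


# --- unknown-week deaths -----------------------------------------------------

def test_adjustment_is_identity_without_unassigned_deaths():
    series = make_uniform_series({2020: {"0-14": 10}})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    adj = adjust_for_unassigned_deaths(rates, {})
    assert adj.m == rates.m
    assert all(f == 1.0 for f in adj.adjustment_factor.values())


def test_adjustment_scales_rate_by_death_ratio():
    series = make_uniform_series({2020: {lab: 900 / 52 for lab in STMF_SCHEME.labels}})
    rates = annualize(series, "TST", "both", 2020,
                      _exposures([2020], exposure=90_000.0))
    assert rates.m["0-14"] == pytest.approx(0.01)
    adj = adjust_for_unassigned_deaths(rates, {"0-14": 100.0})
    assert adj.m["0-14"] == pytest.approx(0.01 * 1000 / 900)
    assert adj.adjustment_factor["0-14"] == pytest.approx(1000 / 900)
    assert adj.m["15-64"] == rates.m["15-64"]


def test_adjustment_with_zero_known_deaths_is_undefined():
    series = make_uniform_series({2020: {}})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    with pytest.raises(ValueError, match="undefined"):
        adjust_for_unassigned_deaths(rates, {"85+": 5.0})


def test_total_unassigned_deaths_allocated_proportionally():
    per = {"0-14": 1, "15-64": 3, "65-74": 2, "75-84": 2, "85+": 2}
    series = make_uniform_series({2020: per})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    adj = adjust_for_unassigned_deaths(rates, {"total": 52.0})
    # every group gets the same relative share, so a common factor
    assert all(f == pytest.approx(1.1) for f in adj.adjustment_factor.values())
    assert sum(adj.D_miss.values()) == pytest.approx(52.0)


@settings(derandomize=True, max_examples=50)
@given(d_miss=st.one_of(st.just(0.0),
                        st.floats(min_value=1.0, max_value=1e4)))
def test_adjustment_never_decreases_rates(d_miss):
    series = make_uniform_series({2020: {lab: 10 for lab in STMF_SCHEME.labels}})
    rates = annualize(series, "TST", "both", 2020, _exposures([2020]))
    adj = adjust_for_unassigned_deaths(rates, {"15-64": d_miss})
    assert all(adj.m[lab] >= rates.m[lab] for lab in STMF_SCHEME.labels)
    assert (adj.m == rates.m) == (d_miss == 0)
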