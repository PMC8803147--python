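import pytest

from stmflife import (STMF_SCHEME, SyntheticConfig, WeeklyRecord, WeeklySeries,
                      hazard_to_reference_table)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def reference_table(default_config):
    """Single-age reference table and true e0 for the default hazard."""
    return hazard_to_reference_table(default_config)


def make_uniform_series(deaths_per_week: dict[int, dict[str, float]],
                        exposure: float = 52_000.0,
                        country: str = "TST", sex: str = "both",
                        weeks=range(1, 53)) -> WeeklySeries:
    """A deterministic weekly series: same group deaths every listed week.

    ``deaths_per_week`` maps year -> {group label -> deaths per week};
    rates are filled from the weekly-rate identity with one exposure for
    every group.
    """
    series = WeeklySeries(scheme=STMF_SCHEME)
    for year, per_group in deaths_per_week.items():
        for w in weeks:
            d = {lab: float(per_group.get(lab, 0.0)) for lab in STMF_SCHEME.labels}
            r = {lab: 52.0 * d[lab] / exposure for lab in STMF_SCHEME.labels}
            series.add(WeeklyRecord(country=country, sex=sex, year=year,
                                    week=w, deaths=d, rates=r))
    return series
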