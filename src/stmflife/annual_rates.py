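"""Annual age-group death rates from weekly counts.

The annual rate for group x is the deaths of weeks 1..52 over the
person-years exposure, equivalently the mean of the 52 annualized weekly
rates m_xw = D_xw/(E_x/52):

    m_x = (sum_w D_xw) / E_x = (1/52) * sum_w m_xw

When the last w-tilde weeks of a year are not yet published (trailing
registration lag), the missing weekly rates are substituted with the same
weeks of a fully observed reference year — a "no excess" best scenario,
not a forecast.  Deaths registered without a known week are folded back in
by scaling each group rate by (D_x + D_x^miss)/D_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .ages import AgeGroupScheme
from .stmf_io import ExposureSet, WeeklySeries


class MissingWeeksError(ValueError):
    """Weeks 1..52 are incomplete; caller should impute from a reference year."""


@dataclass
class AnnualRates:
    """Reconstructed annual death rates for one (country, sex, year).

    Carries full provenance: how many weeks were observed, how many were
    imputed and from which year, and the unknown-week adjustment factor
    applied to each group.
    """

    country: str
    sex: str
    year: int
    scheme: AgeGroupScheme
    m: dict[str, float]                       # annual rate per group label
    D: dict[str, float]                       # deaths with known week
    n_observed_weeks: int = 52
    w_tilde: int = 0                          # number of imputed weeks
    imputation_source_year: int | None = None
    adjustment_factor: dict[str, float] = field(default_factory=dict)
    D_miss: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adjustment_factor:
            self.adjustment_factor = {lab: 1.0 for lab in self.scheme.labels}
        for lab, v in self.m.items():
            if v < 0:
                raise ValueError(f"negative annual rate {v} for group {lab}")
        if self.n_observed_weeks + self.w_tilde != 52:
            raise ValueError("observed plus imputed weeks must equal 52")


def weekly_rate(deaths: float, exposure: float) -> float:
    """Annualized weekly death rate ``m_xw = D_xw / (E_x / 52)``."""
    if exposure <= 0:
        raise ValueError(f"exposure must be positive, got {exposure}")
    if deaths < 0:
        raise ValueError(f"deaths must be nonnegative, got {deaths}")
    return deaths / (exposure / 52.0)


def _week_rate(rec, lab: str, exposure: float) -> float:
    # prefer the published rate; fall back to the identity on counts
    if rec.rates is not None:
        return float(rec.rates[lab])
    return weekly_rate(rec.deaths[lab], exposure)


def annualize(series: WeeklySeries, country: str, sex: str, year: int,
              exposures: ExposureSet, weeks: str = "iso52") -> AnnualRates:
    """Annual rates from a fully observed year.

    ``weeks="iso52"`` (default) uses weeks 1..52 and requires them all,
    matching the 52-week year convention of the weekly series; week 53,
    when present, is ignored.  ``weeks="all"`` sums every week present and
    scales the exposure by (weeks present)/52.
    """
    present = series.weeks(country, sex, year)
    if weeks == "iso52":
        use = [w for w in present if w <= 52]
        missing = sorted(set(range(1, 53)) - set(use))
        if missing:
            raise MissingWeeksError(
                f"weeks {missing} absent for {(country, sex, year)}; "
                f"use impute_missing_weeks")
        frac = 1.0
    elif weeks == "all":
        use = present
        if not use:
            raise MissingWeeksError(f"no weeks at all for {(country, sex, year)}")
        frac = len(use) / 52.0
    else:
        raise ValueError(f"unknown weeks policy {weeks!r}")

    scheme = series.scheme
    m: dict[str, float] = {}
    D: dict[str, float] = {}
    for lab in scheme.labels:
        e = exposures.get(country, sex, year, lab)
        total = sum(series.get(country, sex, year, w).deaths[lab] for w in use)
        D[lab] = total
        m[lab] = total / (e * frac)
    return AnnualRates(country=country, sex=sex, year=year, scheme=scheme,
                       m=m, D=D, n_observed_weeks=52, w_tilde=0)


def impute_missing_weeks(series: WeeklySeries, country: str, sex: str,
                         target_year: int, reference_year: int,
                         exposures: ExposureSet,
                         allow_internal_gaps: bool = False) -> AnnualRates:
    """Annual rates with missing target-year weeks filled from a reference year.

    Operates in annualized-rate space: the reference year's weekly rates
    are reused unchanged for the missing weeks, so

        m_x = (1/52) [ sum of observed target rates
                       + sum of reference rates over the missing weeks ].

    By default the missing weeks must form a trailing block (the
    registration-lag pattern); ``allow_internal_gaps`` lifts that and
    imputes any absent week from the same week of the reference year.
    """
    observed = [w for w in series.weeks(country, sex, target_year) if w <= 52]
    missing = sorted(set(range(1, 53)) - set(observed))
    if not allow_internal_gaps and missing:
        trailing = list(range(53 - len(missing), 53))
        if missing != trailing:
            raise MissingWeeksError(
                f"missing weeks {missing} for {(country, sex, target_year)} are "
                f"not a trailing block; set allow_internal_gaps to impute anyway")
    ref_weeks = set(series.weeks(country, sex, reference_year))
    ref_missing = sorted(set(range(1, 53)) - ref_weeks)
    if ref_missing:
        raise MissingWeeksError(
            f"reference year {reference_year} itself misses weeks {ref_missing}")

    scheme = series.scheme
    m: dict[str, float] = {}
    D: dict[str, float] = {}
    for lab in scheme.labels:
        e_t = exposures.get(country, sex, target_year, lab)
        rate_sum = 0.0
        for w in observed:
            rate_sum += _week_rate(series.get(country, sex, target_year, w), lab, e_t)
        e_r = None
        for w in missing:
            rec = series.get(country, sex, reference_year, w)
            if rec.rates is not None:
                rate_sum += float(rec.rates[lab])
            else:
                if e_r is None:
                    e_r = exposures.get(country, sex, reference_year, lab)
                rate_sum += weekly_rate(rec.deaths[lab], e_r)
        m[lab] = rate_sum / 52.0
        D[lab] = sum(series.get(country, sex, target_year, w).deaths[lab]
                     for w in observed)
    return AnnualRates(country=country, sex=sex, year=target_year, scheme=scheme,
                       m=m, D=D, n_observed_weeks=len(observed),
                       w_tilde=len(missing),
                       imputation_source_year=reference_year if missing else None)


def adjust_for_unassigned_deaths(rates: AnnualRates,
                                 missing: dict[str, float]) -> AnnualRates:
    """Scale each group rate by ``(D_x + D_x^miss) / D_x``.

    ``missing`` maps group labels to unknown-week death counts; the single
    key ``"total"`` is allocated across groups proportionally to the
    known-week deaths ``D_x``.  A group with unknown-week deaths but zero
    known-week deaths has an undefined ratio and raises.
    """
    per_group = {lab: 0.0 for lab in rates.scheme.labels}
    total_extra = 0.0
    for lab, cnt in missing.items():
        if cnt < 0:
            raise ValueError(f"negative unknown-week deaths {cnt} for {lab}")
        if lab == "total":
            total_extra += cnt
        elif lab in per_group:
            per_group[lab] += cnt
        else:
            raise ValueError(f"unknown group label {lab!r} in missing-deaths input")
    if total_extra > 0:
        d_sum = sum(rates.D.values())
        if d_sum <= 0:
            raise ValueError("cannot allocate total unknown-week deaths: "
                             "no known-week deaths at all")
        for lab in per_group:
            per_group[lab] += total_extra * rates.D[lab] / d_sum

    m_adj, factors = {}, {}
    for lab in rates.scheme.labels:
        d, dm = rates.D[lab], per_group[lab]
        if dm > 0 and d <= 0:
            raise ValueError(
                f"group {lab}: {dm} unknown-week deaths but zero known-week "
                f"deaths — adjustment ratio undefined")
        f = (d + dm) / d if d > 0 else 1.0
        factors[lab] = f
        m_adj[lab] = rates.m[lab] * f
    return replace(rates, m=m_adj, D_miss=per_group,
                   adjustment_factor=factors)
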