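"""End-to-end orchestration: weekly series in, e0 drop table out.

For every (country, sex, year) in the input the pipeline annualizes
weekly rates (imputing censored trailing weeks from the reference year
when needed), folds in unknown-week deaths, aggregates separation factors
from the country's single-age reference table, builds the abridged life
table and records e0 with full provenance.  A failure in one year or
country never aborts the rest of the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annual_rates import (MissingWeeksError, adjust_for_unassigned_deaths,
                           annualize, impute_missing_weeks)
from .lifetable import (DropRecord, LifeExpectancyResult,
                        aggregate_separation_factors, build_abridged_lifetable,
                        DEFAULT_RADIX, e0_drop)
from .stmf_io import ExposureSet, SingleAgeLifeTable, WeeklySeries, derive_exposures

log = logging.getLogger("stmflife")


@dataclass
class RunConfig:
    """Everything :func:`run_country` needs besides the weekly series."""

    reference_tables: dict[str, SingleAgeLifeTable]   # country -> nax source
    exposures: ExposureSet | None = None              # derived from rates if None
    missing_deaths: dict[tuple[str, str, int, str], float] = field(default_factory=dict)
    imputation_reference_year: int = 2019
    radix: float = DEFAULT_RADIX
    weeks: str = "iso52"
    allow_internal_gaps: bool = False
    years: list[int] | None = None                    # None = all present
    sexes: list[str] | None = None


@dataclass
class RunReport:
    results: list[LifeExpectancyResult] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _reference_for(config: RunConfig, country: str) -> SingleAgeLifeTable:
    if country in config.reference_tables:
        return config.reference_tables[country]
    if len(config.reference_tables) == 1:
        return next(iter(config.reference_tables.values()))
    raise KeyError(f"no reference life table for {country}")


def run_country(series: WeeklySeries, country: str, config: RunConfig) -> RunReport:
    """Estimate e0 for every (sex, year) of one country.

    Years whose weeks 1..52 are incomplete are imputed from
    ``config.imputation_reference_year``; unimputable years produce an
    error entry and the run continues.
    """
    report = RunReport()
    exposures = config.exposures
    if exposures is None:
        exposures = derive_exposures(series)
    try:
        ref = _reference_for(config, country)
        sep = aggregate_separation_factors(ref, series.scheme)
    except Exception as exc:                          # no nax: country-fatal
        report.errors.append({"country": country, "stage": "nax", "error": str(exc)})
        return report

    sexes = [s for (c, s) in series.groups() if c == country]
    if config.sexes is not None:
        sexes = [s for s in sexes if s in config.sexes]
    for sex in sexes:
        years = series.years(country, sex)
        if config.years is not None:
            years = [y for y in years if y in config.years]
        for year in years:
            try:
                try:
                    rates = annualize(series, country, sex, year, exposures,
                                      weeks=config.weeks)
                except MissingWeeksError:
                    rates = impute_missing_weeks(
                        series, country, sex, year,
                        config.imputation_reference_year, exposures,
                        allow_internal_gaps=config.allow_internal_gaps)
                miss = {lab: cnt for (c, s, y, lab), cnt
                        in config.missing_deaths.items()
                        if (c, s, y) == (country, sex, year)}
                if miss:
                    rates = adjust_for_unassigned_deaths(rates, miss)
                lt = build_abridged_lifetable(rates, sep, radix=config.radix)
                d_known = sum(rates.D.values())
                d_miss = sum(rates.D_miss.values())
                factor = (d_known + d_miss) / d_known if d_known > 0 else 1.0
                res = LifeExpectancyResult(
                    country=country, sex=sex, year=year, e0=lt.e0,
                    w_tilde=rates.w_tilde, adjustment_factor=factor,
                    nax_source=sep.source)
                report.results.append(res)
                log.info("country=%s sex=%s year=%d weeks_obs=%d w_tilde=%d "
                         "adj=%.6f e0=%.4f", country, sex, year,
                         rates.n_observed_weeks, rates.w_tilde, factor, lt.e0)
            except Exception as exc:
                report.errors.append({"country": country, "sex": sex,
                                      "year": year, "error": str(exc)})
                log.warning("country=%s sex=%s year=%d failed: %s",
                            country, sex, year, exc)
    return report


def run_batch(series: WeeklySeries, config: RunConfig) -> RunReport:
    """Run every country present in the series; failures never propagate."""
    report = RunReport()
    for country in sorted({c for (c, _) in series.groups()}):
        sub = run_country(series, country, config)
        report.results.extend(sub.results)
        report.errors.extend(sub.errors)
    return report


def drop_table(results: list[LifeExpectancyResult], base: int = 2019,
               target: int = 2020) -> list[DropRecord]:
    """One :class:`DropRecord` per (country, sex) having both years.

    Pairs missing either year are skipped with a warning; the difference
    is computed on unrounded e0 values.
    """
    by_key: dict[tuple[str, str, int], LifeExpectancyResult] = {}
    for r in results:
        by_key[(r.country, r.sex, r.year)] = r
    drops = []
    for (country, sex) in sorted({(r.country, r.sex) for r in results}):
        prev = by_key.get((country, sex, base))
        curr = by_key.get((country, sex, target))
        if prev is None or curr is None:
            log.warning("skipping %s/%s: missing year %s", country, sex,
                        base if prev is None else target)
            continue
        drops.append(e0_drop(prev, curr))
    return drops


def compare_to_reference(results: list[LifeExpectancyResult],
                         reference: pd.DataFrame) -> dict:
    """Quality check against an external e0 series.

    ``reference`` has columns country, sex, year, e0.  Returns per-key
    absolute differences plus their max and mean.  An empty overlap is an
    error — it means the comparison checked nothing.
    """
    mine = pd.DataFrame([{"country": r.country, "sex": r.sex, "year": r.year,
                          "e0": r.e0} for r in results])
    if mine.empty:
        raise ValueError("no results to compare")
    merged = mine.merge(reference, on=["country", "sex", "year"],
                        suffixes=("", "_ref"))
    if merged.empty:
        raise ValueError("no overlapping (country, sex, year) keys")
    merged["abs_diff"] = (merged["e0"] - merged["e0_ref"]).abs()
    return {
        "detail": merged.sort_values(["country", "sex", "year"]).reset_index(drop=True),
        "max_abs_diff": float(merged["abs_diff"].max()),
        "mean_abs_diff": float(merged["abs_diff"].mean()),
        "n": int(len(merged)),
    }


def results_to_csv(results: list[LifeExpectancyResult]) -> str:
    """Deterministic CSV of results (2-decimal e0 plus full precision)."""
    lines = ["country,sex,year,e0,e0_full,w_tilde,adjustment_factor,nax_source"]
    for r in sorted(results, key=lambda r: (r.country, r.sex, r.year)):
        lines.append(f"{r.country},{r.sex},{r.year},{r.e0:.2f},{r.e0!r},"
                     f"{r.w_tilde},{r.adjustment_factor!r},{r.nax_source}")
    return "\n".join(lines) + "\n"


def drops_to_csv(drops: list[DropRecord]) -> str:
    """Results-table CSV: e0 in both years plus the drop, rounded for display."""
    lines = ["country,sex,e0_prev,e0_curr,difference,"
             "e0_prev_full,e0_curr_full,difference_full"]
    for d in sorted(drops, key=lambda d: (d.country, d.sex)):
        lines.append(f"{d.country},{d.sex},{d.e0_prev:.2f},{d.e0_curr:.2f},"
                     f"{d.difference:.2f},{d.e0_prev!r},{d.e0_curr!r},"
                     f"{d.difference!r}")
    return "\n".join(lines) + "\n"
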