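"""Readers and writers for the STMF weekly dialect and HMD life-table layout.

Two text formats move through this package:

* the STMF output CSV — one row per (country, sex, year, ISO week) with
  death counts ``D<group>`` and annualized weekly rates ``R<group>`` per
  coarse age group, plus totals and bookkeeping flags;
* the HMD 1x1 period life table — whitespace-delimited columns
  ``Year Age mx qx ax lx dx Lx Tx ex`` with ages ``0 .. 110+``.

The STMF dialect never publishes exposures directly, but its annualized
weekly rate is defined as ``m_xw = D_xw / (E_x / 52)``, so the person-years
exposure can be recovered by inverting that identity on any week with
deaths; :func:`derive_exposures` does this and cross-checks that all weeks
of a year imply the same exposure.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import STMF_SCHEME, AgeGroupScheme


class StmfParseError(ValueError):
    """Raised when an STMF CSV violates the dialect."""


class LifeTableParseError(ValueError):
    """Raised when an HMD-layout life table is malformed."""


class ExposureError(ValueError):
    """Raised when exposures cannot be recovered or are inconsistent."""


_SEX_IN = {"b": "both", "f": "female", "m": "male",
           "both": "both", "female": "female", "male": "male"}
_SEX_OUT = {"both": "b", "female": "f", "male": "m"}


def _col_suffix(label: str) -> str:
    """STMF column suffix for an age-group label: ``85+`` -> ``85p``."""
    return label.replace("-", "_").replace("+", "p")


# ---------------------------------------------------------------------------
# weekly series container
# ---------------------------------------------------------------------------

@dataclass
class WeeklyRecord:
    """Deaths and annualized weekly rates for one (country, sex, year, week)."""

    country: str
    sex: str                      # "both" | "female" | "male"
    year: int
    week: int                     # ISO week, 1..53
    deaths: dict[str, float]      # per group label
    rates: dict[str, float] | None = None   # annualized weekly rates, per label
    forecast: bool = False
    split: bool = False
    split_sex: bool = False

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.country, self.sex, self.year, self.week)


@dataclass
class WeeklySeries:
    """An indexed collection of :class:`WeeklyRecord` under one age scheme."""

    scheme: AgeGroupScheme
    records: list[WeeklyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple, WeeklyRecord] = {}
        for rec in self.records:
            self._check(rec)
            self._index[rec.key] = rec

    def _check(self, rec: WeeklyRecord) -> None:
        if not 1 <= rec.week <= 53:
            raise StmfParseError(f"week {rec.week} outside 1..53 for {rec.key}")
        for lab, d in rec.deaths.items():
            if not math.isfinite(d) or d < 0:
                raise StmfParseError(f"negative or non-finite deaths {d} in group "
                                     f"{lab} for {rec.key}")
        if rec.key in getattr(self, "_index", {}):
            raise StmfParseError(f"duplicate record key {rec.key}")

    def add(self, rec: WeeklyRecord) -> None:
        self._check(rec)
        self.records.append(rec)
        self._index[rec.key] = rec

    def get(self, country: str, sex: str, year: int, week: int) -> WeeklyRecord | None:
        return self._index.get((country, sex, year, week))

    def weeks(self, country: str, sex: str, year: int) -> list[int]:
        """Sorted list of weeks present for one (country, sex, year)."""
        return sorted(w for (c, s, y, w) in self._index if (c, s, y) == (country, sex, year))

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (country, sex) pairs present, sorted."""
        return sorted({(c, s) for (c, s, _, _) in self._index})

    def years(self, country: str, sex: str) -> list[int]:
        return sorted({y for (c, s, y, _) in self._index if (c, s) == (country, sex)})

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# STMF CSV
# ---------------------------------------------------------------------------

def parse_stmf_csv(source, scheme: AgeGroupScheme = STMF_SCHEME) -> WeeklySeries:
    """Parse an STMF-dialect CSV into a :class:`WeeklySeries`.

    ``source`` may be a path, a file-like object, or a string containing the
    CSV text itself.  Expected columns: ``CountryCode, Year, Week, Sex``,
    ``D<group>`` per scheme label plus ``DTotal``; optionally ``R<group>``
    and ``RTotal``; optionally ``Split, SplitSex, Forecast``.

    The totals column, when present, is validated against the sum of the
    group columns (tolerance 0.5, absorbing published rounding).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    required = {"CountryCode", "Year", "Week", "Sex"}
    missing = required - set(df.columns)
    if missing:
        raise StmfParseError(f"missing required columns: {sorted(missing)}")

    dcols = {lab: f"D{_col_suffix(lab)}" for lab in scheme.labels}
    for lab, col in dcols.items():
        if col not in df.columns:
            raise StmfParseError(f"missing deaths column {col} for group {lab}")
    rcols = {lab: f"R{_col_suffix(lab)}" for lab in scheme.labels}
    have_rates = all(col in df.columns for col in rcols.values())

    series = WeeklySeries(scheme=scheme)
    for idx, row in df.iterrows():
        week = int(row["Week"])
        deaths = {lab: float(row[dcols[lab]]) for lab in scheme.labels}
        if "DTotal" in df.columns and not pd.isna(row["DTotal"]):
            total = float(row["DTotal"])
            if abs(total - sum(deaths.values())) > 0.5:
                raise StmfParseError(
                    f"row {idx}: DTotal={total} differs from group sum "
                    f"{sum(deaths.values())} by more than 0.5")
        rates = None
        if have_rates:
            rates = {lab: float(row[rcols[lab]]) for lab in scheme.labels}
        sex_raw = str(row["Sex"]).strip().lower()
        if sex_raw not in _SEX_IN:
            raise StmfParseError(f"row {idx}: unknown sex code {row['Sex']!r}")
        rec = WeeklyRecord(
            country=str(row["CountryCode"]).strip(),
            sex=_SEX_IN[sex_raw],
            year=int(row["Year"]),
            week=week,
            deaths=deaths,
            rates=rates,
            forecast=bool(row.get("Forecast", 0)) if "Forecast" in df.columns else False,
            split=bool(row.get("Split", 0)) if "Split" in df.columns else False,
            split_sex=bool(row.get("SplitSex", 0)) if "SplitSex" in df.columns else False,
        )
        series.add(rec)
    return series


def _fmt(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_stmf_csv(series: WeeklySeries) -> str:
    """Render a :class:`WeeklySeries` as canonical STMF CSV text.

    Canonical form: rows sorted by (country, sex, year, week); integral
    counts printed without a decimal point; rates at full precision.
    ``parse_stmf_csv(write_stmf_csv(s))`` reproduces ``s`` exactly.
    """
    scheme = series.scheme
    have_rates = all(r.rates is not None for r in series.records)
    cols = ["CountryCode", "Year", "Week", "Sex"]
    cols += [f"D{_col_suffix(l)}" for l in scheme.labels] + ["DTotal"]
    if have_rates:
        cols += [f"R{_col_suffix(l)}" for l in scheme.labels]
    cols += ["Split", "SplitSex", "Forecast"]

    lines = [",".join(cols)]
    for rec in sorted(series.records, key=lambda r: r.key):
        vals = [rec.country, str(rec.year), str(rec.week), _SEX_OUT[rec.sex]]
        vals += [_fmt(rec.deaths[l]) for l in scheme.labels]
        vals.append(_fmt(sum(rec.deaths[l] for l in scheme.labels)))
        if have_rates:
            vals += [repr(float(rec.rates[l])) for l in scheme.labels]
        vals += [str(int(rec.split)), str(int(rec.split_sex)), str(int(rec.forecast))]
        lines.append(",".join(vals))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# HMD 1x1 life table
# ---------------------------------------------------------------------------

_LT_COLS = ["mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]


@dataclass
class SingleAgeLifeTable:
    """An HMD-layout single-age period life table.

    ``data`` is indexed by integer age 0..omega with columns
    ``mx qx ax lx dx Lx Tx ex``; the last age is the open interval.
    """

    data: pd.DataFrame
    year: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def radix(self) -> float:
        return float(self.data["lx"].iloc[0])

    @property
    def open_age(self) -> int:
        return int(self.data.index[-1])

    @property
    def e0(self) -> float:
        return float(self.data["Tx"].iloc[0] / self.data["lx"].iloc[0])

    def validate(self) -> None:
        df = self.data
        ages = np.asarray(df.index)
        if ages[0] != 0 or not np.array_equal(ages, np.arange(len(ages))):
            raise LifeTableParseError("ages must be contiguous from 0")
        lx = df["lx"].to_numpy(float)
        if np.any(np.diff(lx) > 1e-9 * max(lx[0], 1.0)):
            bad = int(np.argmax(np.diff(lx) > 1e-9 * max(lx[0], 1.0)))
            raise LifeTableParseError(f"lx increases at age {bad + 1}")
        qx = df["qx"].to_numpy(float)
        if np.any(qx < -1e-12) or np.any(qx > 1 + 1e-9):
            raise LifeTableParseError("qx outside [0, 1]")
        n = len(ages)
        atol = max(1.0, 0.75 * n)      # admits integer-rounded published tables
        if abs(df["dx"].sum() - lx[0]) > max(atol, 1e-8 * lx[0]):
            raise LifeTableParseError("sum of dx does not equal the radix")
        t_check = df["Lx"].to_numpy(float)[::-1].cumsum()[::-1]
        if np.max(np.abs(t_check - df["Tx"].to_numpy(float))) > max(atol, 1e-8 * t_check[0]):
            raise LifeTableParseError("Tx is not the reverse cumulative sum of Lx")


def parse_hmd_lifetable(source, year: int | None = None) -> SingleAgeLifeTable:
    """Parse an HMD 1x1 period life table (whitespace- or comma-delimited).

    Skips any preamble before the header row.  ``year`` selects one year
    when the file holds several; with a single year it may be omitted.
    Age tokens are integers with an optional ``+`` on the open age.
    """
    if isinstance(source, str) and "\n" in source:
        text = source
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source, encoding="utf-8").read()

    lines = text.splitlines()
    header_i = None
    for i, line in enumerate(lines):
        toks = line.replace(",", " ").split()
        if "Age" in toks and "lx" in toks:
            header_i = i
            header = toks
            break
    if header_i is None:
        raise LifeTableParseError("no header row with 'Age' and 'lx' found")

    col_pos = {name: header.index(name) for name in ["Age"] + _LT_COLS
               if name in header}
    for name in _LT_COLS:
        if name not in col_pos:
            raise LifeTableParseError(f"missing life-table column {name}")
    year_pos = header.index("Year") if "Year" in header else None

    rows = []
    for line in lines[header_i + 1:]:
        toks = line.replace(",", " ").split()
        if not toks:
            continue
        row_year = int(toks[year_pos]) if year_pos is not None else None
        age_tok = toks[col_pos["Age"]]
        age = int(age_tok.rstrip("+"))
        vals = {name: float(toks[col_pos[name]].rstrip("+")) for name in _LT_COLS}
        rows.append((row_year, age, vals))

    years_present = sorted({y for y, _, _ in rows if y is not None})
    if year is None:
        if len(years_present) > 1:
            raise LifeTableParseError(
                f"file holds years {years_present}; pass year= to select one")
        year = years_present[0] if years_present else None
    rows = [(y, a, v) for y, a, v in rows if year_pos is None or y == year]
    if not rows:
        raise LifeTableParseError(f"no rows for year {year}")

    rows.sort(key=lambda r: r[1])
    ages = [a for _, a, _ in rows]
    if ages != list(range(ages[0], ages[0] + len(ages))):
        raise LifeTableParseError("missing or duplicated ages in life table")
    df = pd.DataFrame([v for _, _, v in rows], index=pd.Index(ages, name="Age"),
                      columns=_LT_COLS)
    return SingleAgeLifeTable(data=df, year=year)


def write_hmd_lifetable(table: SingleAgeLifeTable) -> str:
    """Render a life table in the HMD 1x1 text layout (full precision)."""
    year = table.year if table.year is not None else 0
    out = ["Year Age mx qx ax lx dx Lx Tx ex"]
    last = table.open_age
    for age, row in table.data.iterrows():
        age_tok = f"{age}+" if age == last else str(age)
        vals = " ".join(repr(float(row[c])) for c in _LT_COLS)
        out.append(f"{year} {age_tok} {vals}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

@dataclass
class ExposureSet:
    """Person-years of exposure per (country, sex, year, group label)."""

    values: dict[tuple[str, str, int, str], float] = field(default_factory=dict)

    def get(self, country: str, sex: str, year: int, label: str) -> float:
        key = (country, sex, year, label)
        if key not in self.values:
            raise ExposureError(f"no exposure for {key}")
        e = self.values[key]
        if not e > 0:
            raise ExposureError(f"non-positive exposure {e} for {key}")
        return e

    def set(self, country: str, sex: str, year: int, label: str, value: float) -> None:
        self.values[(country, sex, year, label)] = float(value)


def derive_exposures(series: WeeklySeries,
                     explicit: ExposureSet | None = None,
                     cv_tol: float = 1e-3) -> ExposureSet:
    """Recover exposures from the weekly-rate identity ``E_x = 52 D_xw / m_xw``.

    For each (country, sex, year, group) the estimate is the mean of
    ``52*D/m`` over weeks with both deaths and rate positive.  The STMF
    dialect uses one exposure per year, so the per-week estimates must
    agree: a coefficient of variation above ``cv_tol`` is an error naming
    the offending weeks.  Keys with no eligible week fall back to
    ``explicit`` exposures when given, otherwise raise.
    """
    out = ExposureSet(dict(explicit.values) if explicit is not None else {})
    by_key: dict[tuple, list[tuple[int, float]]] = {}
    for rec in series.records:
        if rec.rates is None:
            continue
        for lab in series.scheme.labels:
            d, m = rec.deaths[lab], rec.rates[lab]
            if d > 0 and m > 0:
                by_key.setdefault((rec.country, rec.sex, rec.year, lab), []).append(
                    (rec.week, 52.0 * d / m))

    for key, ests in by_key.items():
        arr = np.array([e for _, e in ests])
        mean = float(arr.mean())
        cv = float(arr.std() / mean) if len(arr) > 1 else 0.0
        if cv > cv_tol:
            weeks = [w for w, _ in ests]
            raise ExposureError(
                f"inconsistent implied exposures for {key} (CV={cv:.2e}); "
                f"weeks {weeks} imply {sorted(set(np.round(arr, 3)))}")
        out.values.setdefault(key, mean)

    # every (country, sex, year, group) present must end up covered
    for rec in series.records:
        for lab in series.scheme.labels:
            key = (rec.country, rec.sex, rec.year, lab)
            if key not in out.values:
                raise ExposureError(
                    f"no week with positive deaths and rate for {key} and no "
                    f"explicit exposure supplied")
    return out


def read_exposures_csv(source) -> ExposureSet:
    """Read an explicit-exposure CSV: country, sex, year, group, person_years."""
    df = pd.read_csv(source, skipinitialspace=True)
    out = ExposureSet()
    for _, row in df.iterrows():
        sex = _SEX_IN[str(row["sex"]).strip().lower()]
        out.set(str(row["country"]).strip(), sex, int(row["year"]),
                str(row["group"]).strip(), float(row["person_years"]))
    return out


def read_missing_deaths_csv(source) -> dict[tuple[str, str, int, str], float]:
    """Read the unknown-week deaths side CSV: country, sex, year, group, count.

    ``group`` may be a scheme label or the literal ``total`` (allocated
    proportionally downstream).
    """
    df = pd.read_csv(source, skipinitialspace=True)
    out: dict[tuple[str, str, int, str], float] = {}
    for _, row in df.iterrows():
        sex = _SEX_IN[str(row["sex"]).strip().lower()]
        key = (str(row["country"]).strip(), sex, int(row["year"]),
               str(row["group"]).strip())
        out[key] = out.get(key, 0.0) + float(row["count"])
    return out
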