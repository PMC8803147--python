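"""Synthetic weekly-mortality data with a known ground-truth e0.

A parametric hazard — Gompertz senescence plus a Makeham background and a
decaying infant/child component,

    mu(x) = c + a * exp(b x) + a0 * exp(-decay x),

drives everything: a single-age reference life table (fine-grid survival
integration), STMF-style weekly Poisson death counts with multiplicative
cosine seasonality, an optional pandemic shock window, trailing-week
censoring, a fraction of deaths with unknown week, and an independent
individual-level cohort simulation used as the oracle for e0.

All randomness flows from one seed through per-(year, group) sub-streams,
so adding years or groups never reshuffles earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ages import STMF_SCHEME, AgeGroupScheme
from .stmf_io import SingleAgeLifeTable, WeeklyRecord, WeeklySeries

#: integration step in years (<= 1/520, i.e. a tenth of a week)
_STEP = 1.0 / 520.0
#: grid grows in blocks of this many years until survival is exhausted
_GRID_BLOCK = 130.0
#: survival below this is treated as extinct
_SURV_EPS = 1e-10
#: hard cap on the grid; reaching it with live survivors means divergence
_MAX_AGE_HARD = 4000.0


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic country.

    Hazard components are per-year rates; ``seasonal_amplitude`` is the
    relative winter/summer swing of weekly mortality (STMF-like series
    show roughly 10-20%); ``shock_multiplier`` scales group rates inside
    the shock week window, emulating a pandemic wave; ``exposures`` are
    person-years per age-group label.
    """

    makeham_c: float = 4e-4
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.095
    child_a0: float = 4e-3
    child_decay: float = 1.2
    seasonal_amplitude: float = 0.1
    shock_start_week: int = 0
    shock_end_week: int = 0
    shock_multiplier: dict[str, float] = field(default_factory=dict)
    exposures: dict[str, float] = field(default_factory=lambda: {
        lab: 1e7 for lab in STMF_SCHEME.labels})
    censored_trailing_weeks: int = 0
    missing_week_fraction: float = 0.0
    seed: int = 0
    country: str = "SYN"
    sex: str = "both"
    scheme: AgeGroupScheme = STMF_SCHEME

    def __post_init__(self) -> None:
        for name in ("makeham_c", "gompertz_a", "gompertz_b",
                     "child_a0", "child_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if not 0 <= self.missing_week_fraction < 1:
            raise ValueError("missing_week_fraction must be in [0, 1)")
        for lab, e in self.exposures.items():
            if e <= 0:
                raise ValueError(f"exposure for {lab} must be positive")


def hazard(config: SyntheticConfig, x) -> np.ndarray | float:
    """Force of mortality ``mu(x)`` at age(s) ``x`` (per year)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be nonnegative")
    mu = (config.makeham_c
          + config.gompertz_a * np.exp(config.gompertz_b * x)
          + config.child_a0 * np.exp(-config.child_decay * x))
    return mu if mu.ndim else float(mu)


def _survival_grid(config: SyntheticConfig):
    """Fine age grid, survival l(x) (radix 1) and cumulative hazard.

    The grid extends until survival falls below ``_SURV_EPS`` so the
    survival integral (e0) carries no truncation bias even for weak
    hazards; a hazard too small to extinguish the cohort by the hard age
    cap is treated as divergent.
    """
    top = _GRID_BLOCK
    while True:
        grid = np.arange(0.0, top + _STEP / 2, _STEP)
        mu = hazard(config, grid)
        if np.all(mu == 0):
            raise ValueError("all-zero hazard: survival integral diverges")
        lam = np.concatenate([[0.0],
                              np.cumsum((mu[1:] + mu[:-1]) / 2.0 * np.diff(grid))])
        surv = np.exp(-lam)
        if surv[-1] < _SURV_EPS:
            return grid, surv, lam
        if top >= _MAX_AGE_HARD:
            raise ValueError(
                f"survival still {surv[-1]:.2e} at age {top}: the hazard is "
                f"too weak for the e0 integral to converge")
        top = min(top * 2, _MAX_AGE_HARD)


def hazard_to_reference_table(config: SyntheticConfig, open_age: int = 110,
                              radix: float = 100_000.0,
                              year: int | None = None,
                              ) -> tuple[SingleAgeLifeTable, float]:
    """Exact single-age life table for the hazard, plus the true e0.

    Survival is integrated on a fine grid (step 1/520 year); single-age
    l, d, L, a, m, q follow by quadrature and ``true_e0`` is the full
    survival integral.  The table is emitted in the HMD 1x1 layout with
    ages 0..open_age+.
    """
    grid, surv, _ = _survival_grid(config)
    per_year = round(1 / _STEP)

    def integral(i0: int, i1: int) -> float:
        return float(np.trapezoid(surv[i0:i1 + 1], grid[i0:i1 + 1]))

    true_e0 = float(np.trapezoid(surv, grid))

    ages = np.arange(0, open_age + 1)
    l = surv[ages * per_year]
    L = np.empty(len(ages))
    for a in ages[:-1]:
        L[a] = integral(a * per_year, (a + 1) * per_year)
    L[open_age] = integral(open_age * per_year, len(grid) - 1)
    d = np.empty(len(ages))
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(L > 0, d / L, 0.0)
        q = np.empty(len(ages))
        q[:-1] = np.where(l[:-1] > 0, d[:-1] / l[:-1], 0.0)
        q[-1] = 1.0
        ax = np.empty(len(ages))
        ax[:-1] = np.where(d[:-1] > 0, (L[:-1] - l[1:]) / d[:-1], 0.5)
        ax[-1] = L[-1] / l[-1] if l[-1] > 0 else 0.0
    T = L[::-1].cumsum()[::-1]
    ex = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)

    df = pd.DataFrame({
        "mx": m, "qx": q, "ax": ax,
        "lx": l * radix, "dx": d * radix, "Lx": L * radix,
        "Tx": T * radix, "ex": ex,
    }, index=pd.Index(ages, name="Age"))
    table = SingleAgeLifeTable(data=df, year=year, source=f"synthetic:{config.country}")
    return table, true_e0


def group_rates(table: SingleAgeLifeTable, scheme: AgeGroupScheme) -> dict[str, float]:
    """Stationary-population death rates per coarse group: sum(d)/sum(L)."""
    out = {}
    for lab, lo, n in scheme.iter_groups():
        if n is None:
            d = float(table.data["dx"].loc[lo:].sum())
            L = float(table.data["Lx"].loc[lo:].sum())
        else:
            d = float(table.data["dx"].loc[lo:lo + n - 1].sum())
            L = float(table.data["Lx"].loc[lo:lo + n - 1].sum())
        if L <= 0:
            raise ValueError(f"group {lab} has no person-years in the reference")
        out[lab] = d / L
    return out


def seasonal_weights(amplitude: float, n_weeks: int = 52) -> np.ndarray:
    """Mean-one multiplicative weights ``1 + amplitude cos(2 pi (w-1)/52)``."""
    w = np.arange(1, n_weeks + 1)
    s = 1.0 + amplitude * np.cos(2 * np.pi * (w - 1) / n_weeks)
    return s / s.mean()


def _group_rng(seed: int, year: int, group_index: int) -> np.random.Generator:
    # splittable contract: one sub-stream per (year, group)
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(year, group_index)))


def generate_weekly_series(config: SyntheticConfig, years: list[int],
                           ) -> tuple[WeeklySeries, dict[tuple[str, str, int, str], float]]:
    """Poisson weekly death counts in the STMF dialect, plus unknown-week deaths.

    For each year and group the annual rate is the reference table's
    group-aggregated rate; expected weekly deaths are
    ``E_x * m_x * s_w / 52`` with mean-one seasonal weights ``s_w``,
    multiplied by the group's shock multiplier inside the shock window.
    Counts are Poisson.  A binomial ``missing_week_fraction`` of each
    week's deaths is moved to the unknown-week side channel, and the last
    ``censored_trailing_weeks`` weeks of the final year are dropped
    (after their unknown-week deaths were already counted — emulating
    registration without week assignment).

    Returns the series and a dict keyed (country, sex, year, label) of
    unknown-week death counts.
    """
    table, _ = hazard_to_reference_table(config)
    base_rates = group_rates(table, config.scheme)
    s_w = seasonal_weights(config.seasonal_amplitude)
    labels = config.scheme.labels

    deaths = {}    # (year, week, label) -> known-week count
    missing: dict[tuple[str, str, int, str], float] = {}
    for year in years:
        last_year = year == max(years)
        keep_weeks = 52 - (config.censored_trailing_weeks if last_year else 0)
        for gi, lab in enumerate(labels):
            rng = _group_rng(config.seed, year, gi)
            e = config.exposures[lab]
            mult = np.ones(52)
            sm = config.shock_multiplier.get(lab, 1.0)
            if config.shock_start_week >= 1:
                mult[config.shock_start_week - 1:config.shock_end_week] = sm
            lam = e * base_rates[lab] * s_w * mult / 52.0
            counts = rng.poisson(lam)
            if config.missing_week_fraction > 0:
                lost = rng.binomial(counts, config.missing_week_fraction)
                counts = counts - lost
                key = (config.country, config.sex, year, lab)
                missing[key] = missing.get(key, 0.0) + float(lost.sum())
            for w in range(1, 53):
                if w <= keep_weeks:
                    deaths[(year, w, lab)] = float(counts[w - 1])

    series = WeeklySeries(scheme=config.scheme)
    for year in years:
        for w in range(1, 53):
            if (year, w, labels[0]) not in deaths:
                continue
            dw = {lab: deaths[(year, w, lab)] for lab in labels}
            rates = {lab: 52.0 * dw[lab] / config.exposures[lab] for lab in labels}
            series.add(WeeklyRecord(country=config.country, sex=config.sex,
                                    year=year, week=w, deaths=dw, rates=rates))
    return series, missing


def simulate_cohort(config: SyntheticConfig, n: int,
                    seed: int | None = None) -> tuple[float, float]:
    """Mean lifetime of ``n`` simulated individuals, with its standard error.

    Lifetimes are drawn by inverting the cumulative hazard on the fine
    grid (inverse-CDF sampling) — an oracle for e0 that shares no code
    path with the life-table construction beyond the hazard itself.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    grid, _, lam = _survival_grid(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed,
                               spawn_key=(0xC0F0,)))
    u = rng.random(n)
    target = -np.log(u)
    # lifetimes beyond the grid are pinned to its end (survival there ~ 0)
    t = np.interp(target, lam, grid, right=grid[-1])
    mean = float(t.mean())
    se = float(t.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se


def write_truth_json(config: SyntheticConfig, true_e0: float) -> str:
    """Serialize the generating parameters and the true e0 (for comparison)."""
    payload = asdict(config)
    payload["scheme"] = {"lower_bounds": list(config.scheme.lower_bounds),
                         "labels": list(config.scheme.labels)}
    payload["true_e0"] = true_e0
    return json.dumps(payload, indent=2, sort_keys=True)
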