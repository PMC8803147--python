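"""Abridged period life tables and life expectancy at birth.

The pipeline converts annual age-group death rates ``m_x`` into an
abridged life table on the coarse STMF grid.  The m-to-q conversion needs
a separation factor ``nax`` — the average years lived inside (x, x+n) by
those dying there — which is aggregated from a single-age reference life
table via the person-years identity

    nax = (nLx - n * l_{x+n}) / ndx,
    nLx = sum of single-age Lx over the group,  ndx = l_x - l_{x+n}.

With that ``nax`` the classic abridged conversion is

    q = n * m / (1 + (n - a) * m),

the open interval is closed with q = 1, L = l/m (constant hazard), and
e0 = T_0 / l_0.  When both m and nax come from the same reference table
the abridged q reproduces the reference's interval q exactly — the
identity the construction is validated against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AgeGroupScheme
from .annual_rates import AnnualRates
from .stmf_io import SingleAgeLifeTable

DEFAULT_RADIX = 100_000.0


@dataclass
class SeparationFactors:
    """Aggregated ``nax`` per closed group, with provenance.

    ``open_group_e`` records the reference table's remaining life
    expectancy at the open group's lower bound — diagnostic only; at build
    time the open interval uses a = 1/m.
    """

    scheme: AgeGroupScheme
    nax: dict[str, float]
    source: str = ""
    open_group_e: float | None = None


@dataclass
class AbridgedLifeTable:
    """Life table on a coarse age grid; last group open-ended."""

    scheme: AgeGroupScheme
    data: pd.DataFrame     # columns x, n, m, a, q, l, d, L, T, e
    radix: float = DEFAULT_RADIX

    def validate(self, tol: float = 1e-9) -> None:
        """Assert the life-table identities to relative tolerance ``tol``."""
        df = self.data
        scale = self.radix
        assert abs(df["d"].sum() - scale) <= tol * scale, "sum(d) != radix"
        assert np.all(np.diff(df["l"].to_numpy()) <= tol * scale), "l increases"
        assert np.all((df["q"] >= -tol) & (df["q"] <= 1 + tol)), "q outside [0,1]"
        assert abs(df["q"].iloc[-1] - 1.0) <= tol, "open-group q != 1"
        t_check = df["L"].to_numpy()[::-1].cumsum()[::-1]
        assert np.max(np.abs(t_check - df["T"].to_numpy())) <= tol * t_check[0], \
            "T != reverse cumsum of L"
        alive = df["l"] > 0
        e_check = df.loc[alive, "T"] / df.loc[alive, "l"]
        assert np.max(np.abs(e_check - df.loc[alive, "e"])) <= tol * max(df["e"].iloc[0], 1), \
            "e != T/l"
        assert np.all(np.isfinite(df.drop(columns="n").to_numpy())), "non-finite entries"

    @property
    def e0(self) -> float:
        return float(self.data["T"].iloc[0] / self.data["l"].iloc[0])


@dataclass
class LifeExpectancyResult:
    """One estimated e0 with its estimation provenance."""

    country: str
    sex: str
    year: int
    e0: float
    w_tilde: int = 0
    adjustment_factor: float = 1.0
    nax_source: str = ""

    def __post_init__(self) -> None:
        if not self.e0 > 0:
            raise ValueError(f"e0 must be positive, got {self.e0}")


@dataclass
class DropRecord:
    """Year-on-year e0 change; positive difference = a drop."""

    country: str
    sex: str
    e0_prev: float
    e0_curr: float
    difference: float = field(init=False)

    def __post_init__(self) -> None:
        # computed on unrounded values; rendering rounds afterwards
        self.difference = self.e0_prev - self.e0_curr


def aggregate_separation_factors(ref: SingleAgeLifeTable,
                                 scheme: AgeGroupScheme) -> SeparationFactors:
    """Aggregate single-age person-years into per-group ``nax``.

    A closed group with no deaths in the reference (``ndx = 0``) falls
    back to the midpoint ``n/2`` with a warning.
    """
    lx = ref.data["lx"]
    Lx = ref.data["Lx"]
    max_age = ref.open_age
    nax: dict[str, float] = {}
    for lab, lo, n in scheme.iter_groups():
        if n is None:
            continue
        if lo + n > max_age:
            raise ValueError(
                f"reference table (open age {max_age}) does not cover group {lab}")
        nLx = float(Lx.loc[lo:lo + n - 1].sum())
        l_lo = float(lx.loc[lo])
        l_hi = float(lx.loc[lo + n])
        ndx = l_lo - l_hi
        if ndx <= 0:
            warnings.warn(f"group {lab}: no deaths in reference table; "
                          f"falling back to nax = n/2")
            nax[lab] = n / 2.0
        else:
            nax[lab] = (nLx - n * l_hi) / ndx
    open_lo = scheme.lower_bounds[-1]
    open_e = float(ref.data["ex"].loc[open_lo]) if open_lo <= max_age else None
    src = f"{ref.source or 'reference'}:{ref.year}" if ref.year else (ref.source or "reference")
    return SeparationFactors(scheme=scheme, nax=nax, source=src, open_group_e=open_e)


def mx_to_qx(m: float, n: float, a: float) -> float:
    """Probability of dying in an ``n``-year interval given rate ``m``.

    Uses the standard abridged conversion ``q = n m / (1 + (n - a) m)``;
    values above 1 (possible for extreme rates with small ``a``) are
    capped at 1 with a warning.
    """
    if m < 0:
        raise ValueError(f"death rate must be nonnegative, got {m}")
    if not 0 <= a <= n:
        raise ValueError(f"separation factor a={a} outside [0, n={n}]")
    q = n * m / (1.0 + (n - a) * m)
    if q > 1.0:
        warnings.warn(f"q = {q:.4f} > 1 for m={m}, n={n}, a={a}; capping at 1")
        q = 1.0
    return q


def build_abridged_lifetable(rates: AnnualRates | dict[str, float],
                             sep: SeparationFactors,
                             radix: float = DEFAULT_RADIX) -> AbridgedLifeTable:
    """Build the abridged life table from annual group rates.

    Closed groups: ``q`` from :func:`mx_to_qx`, ``d = l q``,
    ``L = n l_{x+n} + a d``.  Open group: ``q = 1``, ``d = l``,
    ``L = l / m`` and ``a = 1/m`` (constant-hazard closure).  ``T`` is the
    reverse cumulative sum of ``L`` and ``e = T / l``.  Identities are
    asserted on every constructed table.
    """
    scheme = sep.scheme
    m = rates.m if isinstance(rates, AnnualRates) else rates
    rows = []
    l_cur = float(radix)
    for lab, lo, n in scheme.iter_groups():
        mx = float(m[lab])
        if n is None:
            if mx <= 0:
                raise ValueError(
                    f"open group {lab} has rate {mx}; the open interval "
                    f"cannot be closed without a positive rate")
            a = 1.0 / mx
            q = 1.0
            d = l_cur
            L = l_cur / mx
        else:
            a = sep.nax[lab]
            q = mx_to_qx(mx, n, a)
            d = l_cur * q
            l_next = l_cur - d
            L = n * l_next + a * d
        rows.append({"x": lo, "n": np.inf if n is None else n, "m": mx,
                     "a": a, "q": q, "l": l_cur, "d": d, "L": L})
        if n is not None:
            l_cur = l_cur - d
    df = pd.DataFrame(rows, index=pd.Index(scheme.labels, name="group"))
    df["T"] = df["L"].to_numpy()[::-1].cumsum()[::-1]
    # remaining expectancy is 0 once the synthetic cohort is extinct
    df["e"] = np.where(df["l"] > 0, df["T"] / np.where(df["l"] > 0, df["l"], 1.0), 0.0)
    lt = AbridgedLifeTable(scheme=scheme, data=df, radix=float(radix))
    lt.validate()
    return lt


def life_expectancy_at_birth(lt: AbridgedLifeTable) -> float:
    """``e0 = T_0 / l_0``."""
    return lt.e0


def e0_drop(prev: LifeExpectancyResult, curr: LifeExpectancyResult) -> DropRecord:
    """The year-on-year e0 difference; positive means a loss of life expectancy.

    Computed on unrounded e0 values (the 2-decimal rendering happens only
    at report time, so the printed difference may differ by 0.01 from the
    difference of the printed e0 columns).
    """
    if (prev.country, prev.sex) != (curr.country, curr.sex):
        raise ValueError(
            f"mismatched series: {(prev.country, prev.sex)} vs "
            f"{(curr.country, curr.sex)}")
    return DropRecord(country=prev.country, sex=prev.sex,
                      e0_prev=prev.e0, e0_curr=curr.e0)
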