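# Methods

## Estimation model

`stmflife` estimates period life expectancy at birth from weekly death
counts published by coarse age group, on the five-group grid
{[0,15), [15,65), [65,75), [75,85), 85+}. The chain is:

1. **Exposure recovery.** The weekly dialect defines the annualized
   weekly rate as m_xw = D_xw/(E_x/52) with a single exposure E_x per
   (country, sex, year, group). Inverting on any week with deaths gives
   E_x = 52·D_xw/m_xw; `derive_exposures` averages over eligible weeks
   and rejects the file if the per-week estimates disagree (coefficient
   of variation above 1e-3), since that indicates the rates were not
   computed under constant exposure and the inversion is invalid.

2. **Annualization.** m_x = (Σ_{w=1..52} D_xw)/E_x, identically
   (1/52)·Σ_w m_xw. The series year is the 52-week year of the weekly
   dialect; a week 53, when present, is parsed and retained but excluded
   from estimation by default (`weeks="all"` instead sums every present
   week and scales the exposure by weeks/52, for sensitivity checks).

3. **Trailing-week imputation.** When the last w̃ weeks of the target
   year are unpublished, their annualized weekly rates are substituted
   with the same weeks of a fully observed reference year:
   m_x = (1/52)[Σ observed target rates + Σ reference rates over the w̃
   missing weeks]. This is a "no-excess best scenario", not a forecast.
   The substitution operates in rate space, so it is correct even when
   exposures differ between the two years. Missing weeks must form a
   trailing block (the registration-lag pattern) unless
   `allow_internal_gaps` is set; the reference year must be complete.

4. **Unknown-week adjustment.** Deaths registered without a week are
   folded back in per group: m_x^adj = m_x·(D_x + D_x^miss)/D_x, where
   D_x counts known-week deaths. When only an ungrouped total is
   available it is allocated to groups proportionally to D_x — a choice,
   documented here, since no principled per-group split exists for an
   ungrouped count. A group with unknown-week deaths but zero known-week
   deaths has an undefined ratio and is an error.

5. **Separation factors.** nax for each closed group is aggregated from
   a single-age reference life table by the person-years identity
   nax = (nLx − n·l_{x+n})/ndx, with nLx the summed single-age Lx over
   the group and ndx = l_x − l_{x+n}. This is the unique value
   satisfying nLx = n·l_{x+n} + nax·ndx, and consequently the only one
   for which rates and factors drawn from the same reference reproduce
   that reference's interval survivorship exactly (tested to 1e-12). A
   deathless closed group falls back to nax = n/2 with a warning rather
   than failing, since the downstream q is 0 regardless of a. The
   reference year is configurable; the natural choice is the most recent
   pre-shock year, and nax is insensitive to it at the 0.01-year level
   because within-group death timing changes slowly.

6. **Abridged life table.** q = n·m/(1 + (n − a)·m) (the classic
   abridged conversion), d = l·q, L = n·l_{x+n} + a·d for closed groups;
   the open group takes q = 1, d = l, L = l/m (constant-hazard closure,
   so its implied a is 1/m). T is the reverse cumulative sum of L and
   e = T/l; e0 = T_0/l_0 at radix 100 000. Identities (Σd = radix,
   T consistency, e = T/l, q ∈ [0,1], l non-increasing) are asserted on
   every constructed table at 1e-9 relative tolerance.

7. **Drop table.** The year-on-year difference e0_prev − e0_curr
   (positive = a drop) is computed on unrounded values and only rounded
   to 2 decimals for display, so a printed difference can legitimately
   differ by 0.01 from the difference of the printed e0 columns. Output
   CSVs carry full-precision companion columns.

## Numerical choices and degenerate inputs

- q values above 1 (extreme rate with small a) are capped at 1 with a
  warning instead of erroring, so severe synthetic shocks flow through.
- A closed group with zero deaths all year gives m = 0 → q = 0 and
  passes through the table legally.
- An open-group rate of 0 is an error: the open interval cannot be
  closed.
- Once a q = 1 group extinguishes the cohort, remaining-life columns are
  reported as 0 rather than 0/0.
- Totals columns in the weekly CSV are validated against the group sum
  with tolerance 0.5 deaths (published rounding); week keys must be
  unique and inside 1..53.

## The synthetic generator

The generator emulates the statistical structure the estimator assumes,
from a known hazard
μ(x) = c + a·e^{bx} + a0·e^{−decay·x}
(Makeham background, Gompertz senescence, decaying childhood component).
Defaults c = 4e-4, a = 3e-5, b = 0.095, a0 = 4e-3, decay = 1.2 give a
true e0 of 77.28 years and group-level death rates (0.0007, 0.0033,
0.024, 0.060, 0.161 per person-year) in the range of contemporary
high-income countries.

- **Reference table / ground truth.** Survival is integrated on a fine
  grid (step 1/520 year, a tenth of a week) that extends until survival
  falls below 1e-10, so the true e0 = ∫l(x)dx carries no truncation
  bias even for weak hazards; single-age l, d, L, a, m follow by
  quadrature and are emitted in the standard 1×1 text layout.
- **Weekly counts.** Group annual rates are the reference table's
  stationary-population rates Σd/ΣL; expected weekly deaths are
  E_x·m_x·s_w/52 with mean-one cosine seasonality
  s_w = 1 + amplitude·cos(2π(w−1)/52) (winter peak at week 1, default
  amplitude 0.1 matching the stylized weekly pattern of such series),
  times a per-group shock multiplier inside the shock week window.
  Counts are Poisson. Default exposure is 1e7 person-years per group —
  a mid-sized country — making Poisson noise on e0 about 0.03 years.
- **Censoring and unknown weeks.** The last w̃ weeks of the final year
  are dropped after generation; a binomial `missing_week_fraction` of
  every week's deaths is moved to an unknown-week side file. Note the
  side file spans all 52 weeks while the published counts, under
  censoring, span 52 − w̃: exactly the mismatch real registration data
  exhibit, and the reason the adjusted, imputed estimate can carry a
  small residual bias (≈0.08 years in the censored study country).
- **Randomness.** A single seed feeds per-(year, group) sub-streams
  (`SeedSequence(seed, spawn_key=(year, group))`), so adding years or
  groups never reshuffles earlier draws.
- **Cohort oracle.** `simulate_cohort` samples lifetimes by inverting
  the cumulative hazard on the fine grid (inverse-CDF sampling) and
  returns the mean and its standard error — an estimate of e0 that
  shares nothing with the life-table construction beyond the hazard,
  used to cross-validate the pipeline within 3 standard errors at
  N = 200 000.

What the generator does **not** emulate: registration-date vs
occurrence-date discrepancies, late-registration revisions, migration,
within-group age drift, or any calibration to a real country. Passing
tests therefore demonstrate the estimator's correctness under its own
assumptions — Poisson counts around a constant-exposure annual rate —
not robustness to those data pathologies.

## Problem sizes

The test suite and the acceptance script run on one synthetic country at
a time: 52 weeks × 5 groups × up to 4 years of Poisson draws at 1e7
person-years per group, a 200 000-individual cohort simulation, and a
~67 000-point survival grid. The full suite completes in well under a
minute; the acceptance script in seconds.

## Known limitations

- Real published e0 series can only be matched to the precision the
  live weekly data themselves allow; the package validates against its
  own generator's ground truth and exposes `compare_to_reference` for
  checking against an external e0 series.
- The proportional allocation of ungrouped unknown-week deaths is an
  assumption; when per-group counts exist they should be supplied.
- No smoothing or graduation of rates and no interval estimates: the
  method produces point estimates, and uncertainty enters only through
  the Monte-Carlo checks in the tests.
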