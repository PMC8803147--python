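# stmflife

Life expectancy at birth from weekly death counts.

Weekly all-cause mortality series in the STMF dialect (Short-Term
Mortality Fluctuations, published alongside the Human Mortality Database)
report deaths by coarse age group — 0–14, 15–64, 65–74, 75–84, 85+ —
within days or weeks of registration, long before annual vital statistics
are final. `stmflife` turns those weekly counts into annual death rates,
abridged period life tables and period life expectancy at birth (e₀), and
tabulates year-on-year e₀ changes — the quantity used to measure how much
a mortality shock such as the COVID-19 pandemic cost a population in life
expectancy. It is written for demographers and epidemiologists who want
the full estimation chain — including its two awkward practical steps,
censored trailing weeks and deaths with no week assignment — as tested,
scriptable code.

## The method

For age group *x* and week *w*, the STMF annualized weekly rate is
*m*ₓ*ᵥᵥ* = *D*ₓ*ᵥᵥ*/(*E*ₓ/52), with *E*ₓ the person-years exposure.
The annual rate is the deaths of weeks 1–52 over the exposure,

&nbsp;&nbsp;&nbsp;&nbsp;*m*ₓ = (Σᵥᵥ *D*ₓᵥᵥ)/*E*ₓ = (1/52) Σᵥᵥ *m*ₓᵥᵥ.

If the last w̃ weeks of the target year are not yet published, their
weekly rates are substituted with the same weeks of a fully observed
reference year (a "no-excess best scenario", not a forecast). Deaths
registered without a known week are folded back in by scaling each group
rate: *m*ₓᵃᵈʲ = *m*ₓ · (*D*ₓ + *D*ₓᵐⁱˢˢ)/*D*ₓ.

The m→q conversion on the coarse grid needs separation factors ₙ*a*ₓ
(mean years lived in the interval by those dying in it), aggregated from
a single-age reference life table via the person-years identity

&nbsp;&nbsp;&nbsp;&nbsp;ₙ*a*ₓ = (ₙ*L*ₓ − *n*·*l*ₓ₊ₙ)/ₙ*d*ₓ,

then *q* = *n m*/(1 + (*n* − *a*) *m*), the open 85+ interval is closed
with *q* = 1 and *L* = *l*/*m*, and e₀ = *T*₀/*l*₀ at radix 100 000.
When both *m* and ₙ*a*ₓ come from the same reference table this
construction reproduces the reference's interval survival exactly — the
identity the test suite pins to 1e−12.

A synthetic-data module generates the whole input side from a known
Gompertz–Makeham-plus-childhood hazard: the exact reference life table
and true e₀ by fine-grid integration, Poisson weekly counts with cosine
seasonality, pandemic-shock windows, trailing-week censoring and
unknown-week thinning — so the pipeline can be validated end to end
against a known answer, with an independent individual-level cohort
simulation as a second oracle.

## Worked example

```python
import stmflife as sl

cfg = sl.SyntheticConfig(seed=0)                      # true e0 = 77.2799
table, true_e0 = sl.hazard_to_reference_table(cfg)
series, _ = sl.generate_weekly_series(cfg, [2019, 2020])

report = sl.run_country(series, "SYN",
                        sl.RunConfig(reference_tables={"SYN": table}))
for r in report.results:
    print(r.year, round(r.e0, 4))
print(sl.pipeline.drops_to_csv(sl.drop_table(report.results)))
```

prints

```
2019 77.2801
2020 77.3162
country,sex,e0_prev,e0_curr,difference,e0_prev_full,e0_curr_full,difference_full
SYN,both,77.28,77.32,-0.04,77.28007341419827,77.31618643488257,-0.036113020684297226
```

With no shock, both years sit
within Poisson noise (about ±0.03 years at 10⁷ person-years of exposure
per group) of the true 77.28, and the "difference" column — positive
would mean a drop — is a statistical zero. Re-running with a 1.5× shock
on the 65+ groups in weeks 10–35 of 2020 (`analysis/01_simulate.py`'s SHK
country) yields e₀ 77.28 → 75.85, a loss of 1.43 years.

The same flow is available from the shell:

```
stmflife simulate --config syn.yaml --out-prefix data/syn
stmflife compute  --stmf data/syn_stmf.csv --lifetables data/syn_lifetable.txt --out results.csv
stmflife drop     --results results.csv --base 2019 --target 2020 --out drops.csv
stmflife compare  --results results.csv --reference hmd_e0.csv --out check.csv
```

`analysis/01_simulate.py` … `04_drop_report.py` run the full study on
three synthetic countries (baseline, shocked, censored-with-unknown-week
deaths) and write their tables under `results/`.

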