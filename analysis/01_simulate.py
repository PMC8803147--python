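#!/usr/bin/env python
"""Generate the three synthetic study countries used by the downstream steps.

* SYN  — baseline Gompertz-Makeham mortality, no shock;
* SHK  — same hazard with a 1.5x shock on the 65+ groups in weeks 10-35
         of 2020 (a stylized pandemic wave);
* CEN  — baseline with the last 4 weeks of 2020 unpublished and 10% of
         deaths lacking a week assignment (registration-lag pattern).

Writes STMF-dialect CSVs, the shared HMD-layout reference life table, the
unknown-week side files and the ground-truth e0 to results/synthetic/.
"""

import json
from pathlib import Path

from stmflife import (SyntheticConfig, generate_weekly_series,
                      hazard_to_reference_table, write_hmd_lifetable,
                      write_stmf_csv)
from stmflife.synthetic import write_truth_json

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
YEARS = [2017, 2018, 2019, 2020]
SEED = 0

CONFIGS = {
    "SYN": SyntheticConfig(seed=SEED, country="SYN"),
    "SHK": SyntheticConfig(seed=SEED, country="SHK",
                           shock_start_week=10, shock_end_week=35,
                           shock_multiplier={"65-74": 1.5, "75-84": 1.5,
                                             "85+": 1.5}),
    "CEN": SyntheticConfig(seed=SEED, country="CEN",
                           censored_trailing_weeks=4,
                           missing_week_fraction=0.1),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, cfg in CONFIGS.items():
        table, true_e0 = hazard_to_reference_table(cfg, year=YEARS[0] - 1)
        # the shock config shares the baseline hazard: one reference table
        if name == "SHK":
            years = YEARS[:-1]
            base, _ = generate_weekly_series(
                SyntheticConfig(seed=SEED, country="SHK"), years)
            shocked, missing = generate_weekly_series(cfg, [2020])
            for rec in shocked.records:
                base.add(rec)
            series = base
        else:
            series, missing = generate_weekly_series(cfg, YEARS)
        (OUT / f"{name}_stmf.csv").write_text(write_stmf_csv(series))
        (OUT / f"{name}_lifetable.txt").write_text(write_hmd_lifetable(table))
        lines = ["country,sex,year,group,count"]
        for (c, s, y, lab), cnt in sorted(missing.items()):
            lines.append(f"{c},{s},{y},{lab},{cnt:g}")
        (OUT / f"{name}_missing.csv").write_text("\n".join(lines) + "\n")
        (OUT / f"{name}_truth.json").write_text(write_truth_json(cfg, true_e0))
        total = sum(sum(r.deaths.values()) for r in series.records)
        print(f"{name}: {len(series)} weekly records, {total:.0f} known-week "
              f"deaths, true e0 = {true_e0:.4f}")


if __name__ == "__main__":
    main()
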