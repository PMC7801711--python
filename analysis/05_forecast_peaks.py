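#!/usr/bin/env python
"""Forecast each site's final-year peak by holding it out of a short series.

Per site, the annual peak-GDD and peak-ordinal-date series (all years but
the last) feed a tiny ARIMA candidate set (mean-only / AR(1) / random
walk, AICc-selected, mean-only mandatory below five training points).  The
held-out year's peak is then predicted on both tracks; the GDD forecast is
converted back to a calendar date with that year's own weather, so both
residuals are reported in days.
"""

import argparse
import warnings
from pathlib import Path

from pbwphen import extract_peak_records, forecast_peak_tables
from pbwphen.simulate import scenario_suite

SITES = ["nagpur", "surat", "raichur", "lam"]
YEARS = 8


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = scenario_suite(SITES, YEARS, 200 + args.seed, mode="thermal")
        records, _ = extract_peak_records(bundle.traps, bundle.weather, bundle.thresholds)
        table = forecast_peak_tables(records, bundle.weather, bundle.thresholds)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "forecast.csv", index=False, float_format="%.2f")
    print(table.to_string(index=False))
    gdd_abs = table["residual_days_gdd"].abs().mean()
    date_abs = table["residual_days_date"].abs().mean()
    print(
        f"\nmean |residual| in days: GDD-track {gdd_abs:.1f} vs date-track {date_abs:.1f}"
        " (thermally driven peaks: the GDD track converts year-specific"
        " weather into the date and should carry the smaller error)"
    )


if __name__ == "__main__":
    main()
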