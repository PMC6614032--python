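"""Report the study's headline numbers from the persisted change table.

Prints, per scenario and future period, the city-average changes in
annual-mean, hottest-month, and coldest-month temperature relative to
the 1988-2017 baseline, together with the exceedance lists (which cities
warm by more than 2 degC in their hottest month; which cities' hottest
month exceeds 40 degC in absolute terms), and writes the headline table
to results/tables/.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import STUDY, TABLES

import urbheat as uh


def main():
    changes = pd.read_csv(STUDY / "changes.csv", dtype={"period": str})
    cities = pd.read_csv(STUDY / "cities.csv")
    TABLES.mkdir(parents=True, exist_ok=True)

    rows = []
    for (scenario, period), sub in changes.groupby(["scenario", "period"], sort=True):
        rows.append({
            "scenario": scenario,
            "period": period,
            "mean_d_annual": sub["d_annual"].mean(),
            "mean_d_hottest": sub["d_hottest"].mean(),
            "mean_d_coldest": sub["d_coldest"].mean(),
            "max_d_hottest": sub["d_hottest"].max(),
        })
    headline = pd.DataFrame(rows)
    headline.to_csv(TABLES / "headline_changes.csv", index=False,
                    float_format="%.6f")
    print("city-average ensemble-mean changes vs the 1988-2017 baseline (degC):")
    print(headline.round(2).to_string(index=False))

    for quantity, cutoff in (("d_hottest", 2.0), ("abs_hottest_future", 40.0)):
        rep = uh.exceedance_report(changes, cities, quantity, cutoff, ">")
        print(f"\ncities with {quantity} > {cutoff:g} degC:")
        for r in rep.frame.itertuples(index=False):
            names = r.cities.split(";") if r.cities else []
            shown = ", ".join(names[:8]) + (" ..." if len(names) > 8 else "")
            print(f"  {r.scenario} {r.period}: {r.count} " + (f"({shown})" if names else ""))
        rep.frame.to_csv(TABLES / f"exceedance_{quantity}_{cutoff:g}.csv", index=False)
    print(f"\ntables -> {TABLES}")


if __name__ == "__main__":
    main()
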