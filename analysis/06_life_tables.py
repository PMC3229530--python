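"""Analysis set 4: Kaplan-Meier life tables over current use.

Cumulative incidence of death and of the composite endpoint (death,
ACS, stroke or heart failure, first of any) at one and three years of
current thiazolidinedione use, overall and by age band and sex, with
excess-risk differences (rosiglitazone minus pioglitazone).  Writes
results/table6_life_tables.csv.
"""

import logging
from pathlib import Path

from tzdcohort import run_life_tables
from tzdcohort.io import read_tables

logging.basicConfig(level=logging.INFO, format="%(message)s")

ROOT = Path(__file__).resolve().parents[1]


def main():
    tables = read_tables(ROOT / "results" / "data")
    t6 = run_life_tables(tables)
    t6.to_csv(ROOT / "results" / "table6_life_tables.csv", index=False,
              float_format="%.4f")

    excess = t6[(t6["endpoint"] == "death")
                & t6["group"].str.contains(" - ")
                & (t6["horizon"] == "3y")]
    print("3-year excess risk of death (rosiglitazone - pioglitazone, "
          "per 100 patients):")
    for _, r in excess.iterrows():
        flag = " (extrapolated)" if r["extrapolated"] else ""
        print(f"  {r['stratum']:<10} {r['incidence_pct']:+.2f}{flag}")


if __name__ == "__main__":
    main()
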