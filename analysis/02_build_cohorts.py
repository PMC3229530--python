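"""Build the study cohorts from the simulated records.

Constructs the overall exposed (prevalent-user) cohort, the per-class
new-user inception cohorts, and age/sex/practice-matched diabetes-free
controls, then reports the cohort sizes and matching yield.  Writes
results/cohorts.csv.
"""

import logging
from pathlib import Path

import pandas as pd

from tzdcohort import (
    MatchCriteria,
    build_exposed_cohort,
    build_inception_cohort,
    match_controls,
)
from tzdcohort.io import read_tables, write_table

logging.basicConfig(level=logging.INFO, format="%(message)s")

ROOT = Path(__file__).resolve().parents[1]
SEED = 20111202
CLASSES = ("metformin", "sulphonylurea", "rosiglitazone", "pioglitazone",
           "insulin")


def main():
    t = read_tables(ROOT / "results" / "data",
                    names=("patients", "prescriptions"))
    patients, rx = t["patients"], t["prescriptions"]

    overall = build_exposed_cohort(patients, rx)
    print(f"overall exposed cohort: {len(overall):,} patients")

    parts = [overall]
    for cls in CLASSES:
        inc = build_inception_cohort(patients, rx, cls)
        parts.append(inc)
        print(f"  inception {cls:<14}: {len(inc):>6,}")

    controls, flagged = match_controls(overall, patients, rx,
                                       MatchCriteria(), seed=SEED)
    unmatched = int((~flagged["matched"]).sum())
    print(f"matched controls: {len(controls):,} "
          f"({unmatched:,} exposed unmatched, flagged not dropped)")
    parts.append(controls)

    cohorts = pd.concat(parts, ignore_index=True)
    write_table(cohorts, "cohorts", ROOT / "results")
    print(f"wrote {ROOT / 'results' / 'cohorts.csv'}")


if __name__ == "__main__":
    main()
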