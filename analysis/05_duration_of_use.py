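"""Analysis set 3: risk of death over duration of current use.

Divides current-use follow-up into 100 equal periods, smooths the
Nelson-Aalen hazard increments with an Epanechnikov kernel
(Ramlau-Hansen estimator), and takes the pointwise ratio of the
rosiglitazone and pioglitazone curves.  Writes
results/hazard_curve.csv and a plot.
"""

import logging
from pathlib import Path

from tzdcohort import run_duration_analysis
from tzdcohort.io import read_tables

logging.basicConfig(level=logging.INFO, format="%(message)s")

ROOT = Path(__file__).resolve().parents[1]


def main():
    tables = read_tables(ROOT / "results" / "data")
    # read the curve only where at least 50 spells remain at risk; the
    # default study's thiazolidinedione cohorts are a few hundred strong
    curve = run_duration_analysis(tables, min_at_risk=50)
    curve.to_csv(ROOT / "results" / "hazard_curve.csv", index=False,
                 float_format="%.6g")
    valid = curve[~curve["masked"]]
    if valid.empty:
        print("no reliably estimable region in the duration curve")
        return
    top = valid.loc[valid["ratio"].idxmax()]
    print(f"{len(valid)} of {len(curve)} duration points estimable "
          "(rest masked for sparse risk sets)")
    print(f"smoothed mortality RR peaks at {top['ratio']:.2f} around "
          f"{top['time'] / 365.25:.2f} years of current use")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(valid["time"] / 365.25, valid["ratio"], lw=2)
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("duration of current use (years)")
        ax.set_ylabel("smoothed crude RR of death\n(rosiglitazone vs pioglitazone)")
        fig.tight_layout()
        fig.savefig(ROOT / "results" / "hazard_curve.png", dpi=120)
        print(f"plot written to {ROOT / 'results' / 'hazard_curve.png'}")
    except Exception as exc:  # plotting is optional
        print(f"plot skipped ({exc})")


if __name__ == "__main__":
    main()
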