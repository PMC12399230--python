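"""Assemble the report bundle: baseline, HRU, cost, sequencing tables,
mean differences with 95% CIs, cost shares, and PPPY conversions.

Reads the upstream results/ files; writes results/report/*.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from claimlines import CodeConfig, build_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    ap.add_argument("--out", default="results/report")
    args = ap.parse_args()

    res = Path(args.results)
    for name in ("cohort.csv", "lines.csv", "summaries.csv", "baseline.csv"):
        if not (res / name).exists():
            raise SystemExit(f"missing upstream file: {res / name}")

    cohort = pd.read_csv(res / "cohort.csv")
    lines = pd.read_csv(res / "lines.csv", parse_dates=["start", "end"])
    summaries = pd.read_csv(res / "summaries.csv")
    baseline = pd.read_csv(res / "baseline.csv")

    tables = build_report(cohort, lines, summaries, baseline, CodeConfig(),
                          out_dir=args.out)
    print(f"wrote {len(tables)} tables -> {args.out}/")
    t3 = tables["table3_costs"]
    overall = t3[(t3.group == "overall") & (t3.measure == "cost_total_pppm")]
    for row in overall.itertuples():
        print(f"  {row.line_number}L mean total cost PPPM: "
              f"${row.mean:,.0f} (n={row.n})")
    for row in tables["progression"].itertuples():
        print(f"  {row.transition}: {row.proportion_pct}%")


if __name__ == "__main__":
    main()
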