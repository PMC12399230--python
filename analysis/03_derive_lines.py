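"""Derive lines of therapy for the selected cohort and tabulate sequencing.

Reads results/data/ and results/cohort.csv; writes results/lines.csv and
results/sequencing.csv and prints per-line regimen-class proportions and
progression shares.
"""

import argparse
from pathlib import Path

import pandas as pd

from claimlines import CodeConfig, derive_cohort_lines, load_dataset, sequencing_matrix
from claimlines.lot_engine import progression_shares


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--cohort", default="results/cohort.csv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    dataset = load_dataset(args.data)
    cohort = pd.read_csv(args.cohort, parse_dates=["first_lc_dx_date",
                                                   "observation_end"])
    codes = CodeConfig()
    lines = derive_cohort_lines(dataset, cohort, codes)
    seq = sequencing_matrix(lines)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    lines.to_csv(out / "lines.csv", index=False)
    seq.to_csv(out / "sequencing.csv", index=False)

    print(seq.to_string(index=False))
    for k, v in progression_shares(lines).items():
        print(f"progression {k}: {100 * v:.1f}%")
    print(f"\n{len(lines)} patient-lines -> {out}/lines.csv")


if __name__ == "__main__":
    main()
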