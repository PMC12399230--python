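"""Apply the proxy cohort-selection algorithm and write the attrition log.

Reads results/data/, writes results/cohort.csv and results/attrition.csv,
and prints the selection flow.
"""

import argparse
from pathlib import Path

from claimlines import CodeConfig, load_dataset, select_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--data-end", default="2023-01-31")
    ap.add_argument("--codes", default=None, help="optional codes TOML")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    dataset = load_dataset(args.data)
    codes = CodeConfig.from_toml(args.codes) if args.codes else CodeConfig()
    cohort, attrition = select_cohort(dataset, codes, args.data_end)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    attrition.to_frame().to_csv(out / "attrition.csv", index=False)

    print(attrition.to_frame().to_string(index=False))
    print(f"\nselected {len(cohort)} patients -> {out}/cohort.csv")


if __name__ == "__main__":
    main()
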