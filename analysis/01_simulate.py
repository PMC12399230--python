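"""Generate the synthetic claims dataset the downstream analyses run on.

Writes the four claim CSVs plus the ground-truth labels under
results/data/.  The default configuration emulates a contemporary
EGFR-mutated advanced NSCLC treated population: ~68% first-line
osimertinib monotherapy, ~42% progression to second line, skewed costs.
"""

import argparse
from pathlib import Path

from claimlines import write_dataset
from claimlines.synthetic_claims import SimulationConfig, generate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=500, help="number of patients")
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    cfg = SimulationConfig(n_patients=args.n, seed=args.seed)
    dataset, truth = generate(cfg)
    out = Path(args.out)
    write_dataset(dataset, out)
    truth.patients.to_csv(out / "truth_patients.csv", index=False)
    truth.lines.to_csv(out / "truth_lines.csv", index=False)

    n_elig = int(truth.patients.eligible.sum())
    print(f"simulated {args.n} patients (seed {args.seed}) -> {out}/")
    print(f"  medical claims : {len(dataset.medical):>7}")
    print(f"  pharmacy claims: {len(dataset.pharmacy):>7}")
    print(f"  truly eligible : {n_elig} ({100 * n_elig / args.n:.1f}%)")


if __name__ == "__main__":
    main()
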