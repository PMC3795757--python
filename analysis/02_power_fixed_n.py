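#!/usr/bin/env python
"""Power at a fixed cohort size as contamination grows.

The fixed-size design: 10,000 cases and 10,000 controls per replicate,
trend test at genome-wide alpha = 5e-8, across the admixture grid.  The
Monte-Carlo estimate is reported next to the analytic non-central
chi-square power.  Writes results/power_fixed_n.tsv.
"""

import argparse

import pandas as pd

from hetgwas import ModelSpec, SimConfig, analytic_power, mc_power
from hetgwas.io import write_results

BETAS = [round(0.1 * i, 1) for i in range(10)]
N = 10_000


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=200,
                    help="Monte-Carlo replicates per cell.")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, reps=args.reps, test="catt")
    rows = []
    for model in ("dominant", "multiplicative"):
        for rr in (1.1, 1.2, 1.3):
            spec = ModelSpec(model, 0.01, 0.2, rr)
            for beta in BETAS:
                est = mc_power(spec, beta, N, N, cfg)
                rows.append(
                    {
                        "model": model, "rr": rr, "beta": beta,
                        "mc_power": est.power, "mc_se": est.mc_se,
                        "analytic_power": analytic_power(spec, beta, N, N),
                    }
                )
    table = pd.DataFrame(rows)
    write_results(
        table,
        "results/power_fixed_n.tsv",
        {"seed": args.seed, "reps": args.reps, "n_case": N, "n_control": N,
         "alpha": 5e-8, "prevalence": 0.01, "maf": 0.2},
    )
    print(f"wrote results/power_fixed_n.tsv ({len(table)} rows)")
    half = table[(table.beta == 0.5) & (table.rr == 1.2)]
    clean = table[(table.beta == 0.0) & (table.rr == 1.2)]
    print(
        "finding: at 10,000/10,000 and RR 1.2 (MAF 0.2), power falls from "
        f"~{clean.analytic_power.mean():.2f} with clean cases to "
        f"~{half.analytic_power.mean():.2f} at 50% contamination — the loss "
        "is disproportionately larger than the contaminated fraction."
    )


if __name__ == "__main__":
    main()
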