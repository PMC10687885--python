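#!/usr/bin/env python
"""Case-mix indices and coefficients of variation per RUG-III/HC group.

Builds the per-group CMI/CV tables for the full and operational samples from
the episode measures of 03_account_resources.py, checks the normalization
identity (n-weighted mean CMI = 1), and writes both tables under results/.
"""

import pandas as pd

from rughc import case_mix_table
from rughc.taxonomy import MEASURES

OUTDIR = "results"


def main() -> None:
    for label in ("full", "operational"):
        measures = pd.read_csv(f"{OUTDIR}/measures_{label}.csv")
        table = case_mix_table(measures, label)
        table.data.to_csv(f"{OUTDIR}/casemix_{label}.csv")

        groups = table.data.drop("Overall")
        checks = []
        for m in MEASURES:
            filled = groups.dropna(subset=[f"cmi_{m}"])
            checks.append((filled["n"] * filled[f"cmi_{m}"]).sum() / table.n_total)
        print(f"\n{label} sample (n = {table.n_total}): "
              f"n-weighted mean CMI per measure = "
              + ", ".join(f"{c:.6f}" for c in checks))
        print(table.formatted().to_string())
    print(f"\n-> {OUTDIR}/casemix_full.csv, {OUTDIR}/casemix_operational.csv")


if __name__ == "__main__":
    main()
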