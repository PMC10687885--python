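#!/usr/bin/env python
"""Variance in resource utilization explained by the case-mix system.

Regresses each episode's utilization measure on its group's CMI (refit
within each sample), with and without a program indicator, for the full and
operational samples: 4 measures x 2 models x 2 samples. Writes the R^2 grid
under results/ and summarizes the qualitative pattern.
"""

import pandas as pd

from rughc import evaluation_table

OUTDIR = "results"


def main() -> None:
    full = pd.read_csv(f"{OUTDIR}/measures_full.csv")
    oper = pd.read_csv(f"{OUTDIR}/measures_operational.csv")
    table = evaluation_table(full, oper, refit_cmi=True)
    table = table.assign(r_squared_pct=(100 * table["r_squared"]).round(2))
    table.to_csv(f"{OUTDIR}/evaluation.csv", index=False)

    wide = table.pivot_table(index="measure", columns=["model", "sample"],
                             values="r_squared_pct")
    print("variance explained (R^2, %):")
    print(wide.round(2).to_string())

    nested_ok = all(
        sub.set_index("model")["r_squared"]["cmi_plus_program"]
        >= sub.set_index("model")["r_squared"]["cmi_only"] - 1e-10
        for _, sub in table.groupby(["measure", "sample"])
    )
    print(f"\nprogram indicator never lowers R^2: {nested_ok}")
    paid = table[(table.measure == "paid_hours") & (table.model == "cmi_only")]
    total = table[(table.measure == "total_hours") & (table.model == "cmi_only")]
    print("combined paid+unpaid time explained vs paid time only: "
          f"{total.r_squared_pct.mean():.2f}% vs {paid.r_squared_pct.mean():.2f}%")
    print(f"-> {OUTDIR}/evaluation.csv")


if __name__ == "__main__":
    main()
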