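#!/usr/bin/env python
"""Fit the metal toxicity curves and tabulate EC50 estimates.

Reads the simulated viability tables from results/simulated/, fits the
four-parameter logistic on log dose (log-response least squares) and writes
results/ec50_fits.csv with EC50, its standard error, the hill slope and r2.
"""

from pathlib import Path

import pandas as pd

from phenolstress import dose_response as dr

SIM = Path("results/simulated")
TRUE_EC50S = {"Cd": 2.7, "Cu": 16.0, "Co": 190.7}


def main() -> None:
    rows = []
    for metal, true_ec50 in TRUE_EC50S.items():
        tab = dr.read_dose_response(SIM / f"dose_response_{metal}.csv")
        res = dr.fit(tab)
        rows.append({"metal": metal, "ec50_ppm": res.ec50,
                     "se_ec50": res.se_ec50, "hill": res.hill, "r2": res.r2,
                     "true_ec50_ppm": true_ec50,
                     "rel_error_pct": 100 * (res.ec50 - true_ec50) / true_ec50})
        print(f"{metal}: EC50 = {res.ec50:.3g} +- {res.se_ec50:.2g} ppm "
              f"(generated at {true_ec50}), hill = {res.hill:.2f}, "
              f"r2 = {res.r2:.4f}")
    out = Path("results/ec50_fits.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
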