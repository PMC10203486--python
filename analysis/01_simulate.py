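#!/usr/bin/env python
"""Generate the synthetic multi-treatment study and the dose-response assays.

Emulates the experimental design: a shared CHNOS formula library measured as
negative-mode peak lists (three chromatographic fractions, technical
duplicates, shared blank) for a control culture (triplicate) and three
metal treatments (duplicates) with planted phenolic intensity shares, plus
duplicate 8-dose viability curves for Cd, Cu and Co at their literature
EC50s. Everything is written under results/simulated/.
"""

import sys
from pathlib import Path

import pandas as pd

from phenolstress import synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path("results/simulated")

EC50S = {"Cd": 2.7, "Cu": 16.0, "Co": 190.7}   # ppm, exposure-assay targets


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exp = synthetic.simulate_experiment(seed=SEED, n_formulas=300, out_dir=OUT)
    n_samples = sum(len(b) for b in exp["groups"].values())
    print(f"peak lists: {n_samples} biological samples x 3 fractions x 2 "
          f"technical replicates -> {OUT}")
    print("planted phenolic intensity shares (%):",
          {g: round(v, 3) for g, v in exp["planted_actual"].items()})

    for i, (metal, ec50) in enumerate(EC50S.items()):
        tab = synthetic.generate_dose_response(
            ec50=ec50, hill=2.0, top=1.0e6, n_doses=8, noise_cv=0.1,
            seed=SEED + i)
        pd.DataFrame({"dose_ppm": tab.doses, "response": tab.responses,
                      "replicate": tab.replicate}).to_csv(
            OUT / f"dose_response_{metal}.csv", index=False)
        print(f"dose-response {metal}: 8 doses x 2 replicates around "
              f"EC50 {ec50} ppm")


if __name__ == "__main__":
    main()
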