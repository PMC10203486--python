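#!/usr/bin/env python
"""Summarize the mass-difference metabolite networks per treatment.

The networks (nodes = phenolic m/z, edges = pairwise mass differences
matching the built-in transformation table within +-2 ppm of the larger
member) were written by the pipeline run; this script tabulates distinct
transformations and heteroatom-group abundance profiles (group 1 sulfur,
2 nitrogen, 3 nitrogen+oxygen, 4 oxygen) and the most frequent
transformations per treatment.
"""

from pathlib import Path

import pandas as pd

PROCESSED = Path("results/processed")


def main() -> None:
    summ = pd.read_csv(PROCESSED / "network_summaries.csv")
    print(summ.round(3).to_string(index=False))
    for edge_file in sorted(PROCESSED.glob("network_*_edges.csv")):
        group = edge_file.stem.replace("network_", "").replace("_edges", "")
        edges = pd.read_csv(edge_file)
        if edges.empty:
            print(f"\n{group}: no edges")
            continue
        top = edges["transformation"].value_counts().head(5)
        print(f"\n{group}: {len(edges)} edges, "
              f"{edges['transformation'].nunique()} distinct transformations; "
              "most frequent:")
        for name, count in top.items():
            print(f"    {name}: {count}")


if __name__ == "__main__":
    main()
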