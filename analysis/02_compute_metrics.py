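#!/usr/bin/env python
"""Compute structural descriptors for every web in a collection.

Reads the edge lists written by 01_simulate_collection.py (or any
directory of webs), applies the inclusion filter (>= 25 species, >= 50
links), computes the descriptor vector per web, and screens for
collinear descriptor pairs.  Writes metrics.csv and screen.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from foodwebsem import filter_webs, metrics_row, read_edgelist
from foodwebsem.metrics import correlation_screen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--webs", type=Path, default=Path("scratch/collection"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    files = sorted(args.webs.glob("*.tsv"))
    webs = filter_webs([read_edgelist(p) for p in files])
    rows = [metrics_row(w) for w in webs]
    table = pd.DataFrame([r.to_dict() for r in rows])
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "metrics.csv", index=False)

    screen = pd.DataFrame(correlation_screen(rows))
    screen.to_csv(args.out / "screen.csv", index=False)
    flagged = screen[screen["flagged"]]
    print(f"{len(webs)} webs passed the inclusion filter "
          f"({len(files) - len(webs)} removed)")
    print(table[["S", "L", "C", "p_basal", "omnivory", "maxTL"]]
          .describe().loc[["mean", "std"]].round(3).to_string())
    print("\ncollinear descriptor pairs (|r| >= 0.7):")
    for _, row in flagged.iterrows():
        print(f"  {row.col_a} ~ {row.col_b}: r = {row.r:+.3f}")
    print("default SEM variable set drops p_intermediate and meanTL.")


if __name__ == "__main__":
    main()
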