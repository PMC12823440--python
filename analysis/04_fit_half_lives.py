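#!/usr/bin/env python
"""Fit reporter half-lives from the CHX (translation-shutoff) trajectories.

Each cell line's CHX POC time course follows 100 * exp(-tau t) once
synthesis stops; nonlinear least squares recovers tau and the half-life
ln(2)/tau.  Compares every fit against the generator's planted
half-life.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kindeg.halflife import half_life_table
from kindeg.io import read_screen_table, write_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    poc_path = ROOT / "scratch" / "poc.tsv"
    if not poc_path.exists():
        raise SystemExit("run analysis/02_normalize_prescreen.py first")
    poc = read_screen_table(poc_path, "poc")
    fits = half_life_table(poc)

    panel = pd.read_csv(ROOT / "results" / "reporter_panel.tsv", sep="\t")
    merged = fits.merge(
        panel[["cell_line_id", "half_life_h"]].rename(columns={"half_life_h": "true_h"}),
        on="cell_line_id",
    )
    merged["rel_err"] = (merged["half_life_h"] - merged["true_h"]).abs() / merged["true_h"]
    write_table(merged, ROOT / "results" / "half_lives.tsv")

    print(f"fitted {len(merged)} reporters; "
          f"median |rel err| {100 * merged['rel_err'].median():.2f}%, "
          f"max {100 * merged['rel_err'].max():.2f}%")
    for line in ("GFP", "dGFP"):
        row = merged.set_index("cell_line_id").loc[line]
        print(f"  {line}: fitted {row['half_life_h']:.2f} h (true {row['true_h']:.2f} h)")


if __name__ == "__main__":
    main()
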