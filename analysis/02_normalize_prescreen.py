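#!/usr/bin/env python
"""Normalize raw luminescence to POC and run the library prescreen.

Per plate and timepoint: intraplate median-polish correction, then POC
scaling against the trimmed DMSO (100%) and CHIR-99021 (0%) anchors.
The prescreen evaluates every compound on the GFP/dGFP control lines at
two concentrations (any POC < 48 or > 150, or > 58% drift from the 2-h
timepoint, fails) and should flag exactly the planted toxic compounds.
"""

from pathlib import Path

from kindeg.io import read_screen_table, write_table
from kindeg import normalize as nz

ROOT = Path(__file__).resolve().parents[1]


def main():
    raw_path = ROOT / "scratch" / "raw_screen.tsv"
    if not raw_path.exists():
        raise SystemExit("run analysis/01_simulate_screen.py first")
    raw = read_screen_table(raw_path, "raw")
    poc = nz.normalize_screen(raw)
    write_table(poc, ROOT / "scratch" / "poc.tsv")

    verdicts = nz.prescreen_compounds(poc)
    write_table(verdicts, ROOT / "results" / "prescreen_verdicts.tsv")
    failed = verdicts[~verdicts["passed"]]
    print(f"normalized {len(poc):,} measurements on "
          f"{poc['plate_id'].nunique()} plates")
    print(f"prescreen: {len(failed)} of {len(verdicts)} compounds eliminated: "
          f"{sorted(failed['compound_id'])}")
    low = verdicts[verdicts["passed"] & (verdicts["concentration_um"] < 10.0)]
    print(f"{len(low)} compounds fell back to the lower concentration")


if __name__ == "__main__":
    main()
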