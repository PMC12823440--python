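#!/usr/bin/env python
"""Generate the synthetic temporal degradation screen.

Emulates the study panel: 88 canonical + 10 mutant kinase Nluc reporter
lines plus GFP/dGFP controls, a ~1,600-compound library with DMSO /
CHIR-99021 / CHX / NVP-2 control wells and 10 PROTAC true positives,
timepoints 2/6/10/14/18 h, two technical replicates, 5% multiplicative
well noise and smooth plate gradients.  Plants 200 degraders, 150
stabilizers and 10 toxic compounds as ground truth.

Writes the large raw table and ground-truth tables under scratch/ (they
are regenerated on demand) and a small panel summary under results/.
"""

import sys
from pathlib import Path

from kindeg import simulate as sim
from kindeg.io import write_table

SEED = 20260920
ROOT = Path(__file__).resolve().parents[1]


def main():
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    cfg = sim.ScreenConfig(n_planted_degraders=200, n_planted_stabilizers=150)
    raw, truth = sim.generate_screen(cfg, seed)

    scratch = ROOT / "scratch"
    write_table(raw, scratch / "raw_screen.tsv")
    write_table(truth.effects, scratch / "ground_truth_effects.tsv")
    write_table(truth.kinase_annotation(), scratch / "kinase_annotation.tsv")
    write_table(truth.compound_annotation(), scratch / "compound_annotation.tsv")

    summary = truth.reporters.assign(seed=seed)
    write_table(summary, ROOT / "results" / "reporter_panel.tsv")

    n_eff = truth.effects["class_label"].value_counts().to_dict()
    print(f"generated {len(raw):,} raw measurements "
          f"({truth.reporters.shape[0]} lines x {truth.compounds.shape[0]} compounds, seed {seed})")
    print(f"planted effects: {n_eff}")
    print(f"wrote scratch/raw_screen.tsv and results/reporter_panel.tsv")


if __name__ == "__main__":
    main()
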