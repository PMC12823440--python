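#!/usr/bin/env python
"""Downstream statistics of the binary hit map.

Selectivity breakdown, HSP90-client enrichment among downregulated
kinases (the generator plants degraders preferentially on client
kinases, so the strong/weak-vs-non odds ratios should exceed 1),
binding-mode enrichment (modes are assigned independently of the
planted effects, so no association is expected), the half-life vs
scoring-frequency Spearman correlation, and mutant/canonical hit-profile
Jaccard distances.
"""

from pathlib import Path

import pandas as pd

from kindeg import atlas
from kindeg.io import write_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    scratch = ROOT / "scratch"
    if not (scratch / "degradation_hits.tsv").exists():
        raise SystemExit("run analysis/03_score_and_call_hits.py first")
    hits = pd.read_csv(scratch / "degradation_hits.tsv", sep="\t").set_index(
        ["cell_line_id", "compound_id"]
    )
    hit_matrix = pd.read_csv(scratch / "hit_matrix.csv", index_col=0)
    kin_ann = pd.read_csv(scratch / "kinase_annotation.tsv", sep="\t")
    cpd_ann = pd.read_csv(scratch / "compound_annotation.tsv", sep="\t")
    half_lives = pd.read_csv(ROOT / "results" / "half_lives.tsv", sep="\t")

    counts, selective = atlas.selectivity_table(hits)
    write_table(selective, ROOT / "results" / "selective_pairs.tsv")
    print(f"{len(selective)} selective pairs "
          f"({counts['selective'].sum()} of {len(counts)} hit compounds hit one kinase)")

    client = pd.DataFrame([r.as_dict() for r in atlas.client_enrichment(hit_matrix, kin_ann)])
    write_table(client, ROOT / "results" / "client_enrichment.tsv")
    strong_non = client.query("label_a == 'strong' and label_b == 'non'").iloc[0]
    print(f"HSP90 strong-vs-non clients: OR {strong_non['odds_ratio']:.2f}, "
          f"p {strong_non['p_value']:.2e}")

    modes = pd.DataFrame([
        r.as_dict() for r in atlas.binding_mode_enrichment(
            set(counts["compound_id"]), cpd_ann)
    ])
    write_table(modes, ROOT / "results" / "binding_mode_enrichment.tsv")
    for _, r in modes.iterrows():
        print(f"binding mode {r['label_a']}: OR {r['odds_ratio']:.2f}, p {r['p_value']:.3f}")

    kin_hl = half_lives[~half_lives.cell_line_id.isin(["GFP", "dGFP"])]
    freq = (hits[hits["hit"]].groupby("cell_line_id").size()
            .reindex(kin_hl["cell_line_id"]).fillna(0))
    rho, p = atlas.halflife_scoring_correlation(kin_hl, freq)
    print(f"half-life vs scoring frequency: Spearman rho {rho:.3f} (p {p:.4f})")

    mw = atlas.mutant_wt_comparison(hits, kin_ann, half_lives)
    write_table(mw, ROOT / "results" / "mutant_wt.tsv")
    if len(mw):
        print(f"mutant/WT pairs: median JD {mw['jaccard_distance'].median():.2f}, "
              f"{(mw['jaccard_distance'] >= 0.8).sum()} of {len(mw)} with JD >= 0.8")

    pd.DataFrame([{"spearman_rho": rho, "p_value": p, "n_kinases": len(kin_hl)}]).pipe(
        write_table, ROOT / "results" / "halflife_correlation.tsv"
    )


if __name__ == "__main__":
    main()
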