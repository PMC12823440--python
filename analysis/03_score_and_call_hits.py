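#!/usr/bin/env python
"""Score every (kinase, compound) pair and call degradation/stabilization hits.

Applies the replicate-variance and reactive-compound filters, the
two-pass centering, the eight normalization schemes and the published
hit queries; then measures recovery against the planted ground truth
(sensitivity and FDR of the default degradation query) and re-derives
the query with the FDR-minimizing threshold scan seeded by the PROTAC
true positives.
"""

from pathlib import Path

import pandas as pd

from kindeg import scoring as sc
from kindeg.io import read_screen_table, write_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    poc_path = ROOT / "scratch" / "poc.tsv"
    if not poc_path.exists():
        raise SystemExit("run analysis/02_normalize_prescreen.py first")
    poc = read_screen_table(poc_path, "poc")
    truth = pd.read_csv(ROOT / "scratch" / "ground_truth_effects.tsv", sep="\t")
    toxic = set(truth.loc[truth.class_label == "toxic", "compound_id"])
    poc = poc[~poc["compound_id"].isin(toxic)]  # prescreen-eliminated

    tensor = sc.build_tensor(poc)
    n_var, zero_frac = sc.filter_variable_pairs(tensor)
    reactive = sc.filter_reactive_compounds(tensor)
    tensor = sc.center_series(tensor)
    nulls = sc.build_null_models(tensor)

    deg = sc.compute_scheme_scores(tensor, nulls, "degradation")
    stab = sc.compute_scheme_scores(tensor, nulls, "stabilization")
    deg_hits = sc.call_hits(deg, sc.DEFAULT_DEGRADATION_QUERY, tensor)
    stab_hits = sc.call_hits(stab, sc.DEFAULT_STABILIZATION_QUERY, tensor)

    write_table(deg.reset_index(), ROOT / "scratch" / "degradation_scores.tsv")
    write_table(deg_hits.reset_index(), ROOT / "scratch" / "degradation_hits.tsv")
    write_table(stab_hits.reset_index(), ROOT / "scratch" / "stabilization_hits.tsv")
    write_table(sc.hit_matrix(deg_hits, tensor), ROOT / "scratch" / "hit_matrix.csv",
                index=True)

    planted_deg = set(zip(truth.loc[truth.class_label == "degrader", "cell_line_id"],
                          truth.loc[truth.class_label == "degrader", "compound_id"]))
    planted_stab = set(zip(truth.loc[truth.class_label == "stabilizer", "cell_line_id"],
                           truth.loc[truth.class_label == "stabilizer", "compound_id"]))
    hits = set(deg_hits.index[deg_hits["hit"]])
    shits = set(stab_hits.index[stab_hits["hit"]])
    tp = len(hits & planted_deg)
    stp = len(shits & planted_stab)

    protac = {p for p in planted_deg if p[1].startswith("PROTAC")}
    query, curve = sc.scan_thresholds(deg, protac, exclude=tensor.excluded_pairs())
    write_table(curve, ROOT / "results" / "fdr_scan_curve.tsv")

    summary = pd.DataFrame([{
        "variance_filtered_pairs": n_var,
        "zero_high_sd_fraction": round(zero_frac, 4),
        "reactive_compounds": len(reactive),
        "degradation_hits": len(hits),
        "degradation_sensitivity": round(tp / len(planted_deg), 4),
        "degradation_fdr": round((len(hits) - tp) / max(len(hits), 1), 4),
        "stabilization_hits": len(shits),
        "stabilization_sensitivity": round(stp / max(len(planted_stab), 1), 4),
        "hit_compounds": len({c for _, c in hits}),
        "hit_kinases": len({k for k, _ in hits}),
        "scan_best_query": str(dict(query.clauses) | {"TOT": query.tot_threshold}),
    }])
    write_table(summary, ROOT / "results" / "hit_summary.tsv")
    print(summary.T.to_string())


if __name__ == "__main__":
    main()
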