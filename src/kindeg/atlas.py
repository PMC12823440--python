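"""Downstream statistics of the binary degradation hit map.

Selectivity (compounds hitting exactly one kinase), Jaccard distances
between kinase hit profiles, HSP90-client and binding-mode enrichment
(two-sided Fisher's exact tests), the half-life vs scoring-frequency
Spearman correlation, and mutant/wild-type profile comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "selectivity_table",
    "jaccard_distance",
    "client_enrichment",
    "binding_mode_enrichment",
    "halflife_scoring_correlation",
    "mutant_wt_comparison",
]

HSP90_CATEGORIES = ("strong", "weak", "non", "not_defined")


@dataclass
class EnrichmentResult:
    """2x2 association: sample (cross-product) odds ratio + exact p-value."""

    label_a: str
    label_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float          # sample OR; inf flagged via `infinite`
    p_value: float
    infinite: bool = False
    conditional_or: float = float("nan")  # conditional MLE, logged alongside

    def as_dict(self):
        (a, b), (c, d) = self.table
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": self.odds_ratio, "p_value": self.p_value,
            "infinite_or": self.infinite, "conditional_or": self.conditional_or,
        }


def _fisher(table, label_a="", label_b="") -> EnrichmentResult:
    (a, b), (c, d) = table
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        or_ = math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
        inf = math.isinf(or_)
    else:
        or_, inf = (a * d) / (b * c), False
    try:
        cond = float(_cond_odds_ratio([[a, b], [c, d]]).statistic)
    except Exception:  # degenerate margins
        cond = float("nan")
    return EnrichmentResult(label_a, label_b, ((a, b), (c, d)), or_, float(p), inf, cond)


def selectivity_table(hits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound kinase-hit counts and the selective-pair list.

    ``hits`` is a hit table indexed by (cell_line_id, compound_id) with a
    boolean ``hit`` column.  A pair is selective iff its compound hits
    exactly one kinase line.  Returns (per-compound counts with a
    ``selective`` flag, the selective pair list).
    """
    h = hits[hits["hit"]]
    per_comp = h.groupby("compound_id").size().rename("n_kinases_hit")
    sel_comps = per_comp.index[per_comp == 1]
    sel = h[h.index.get_level_values("compound_id").isin(sel_comps)]
    selective = sel.reset_index()[["cell_line_id", "compound_id"]]
    counts = pd.DataFrame(per_comp).reset_index()
    counts["selective"] = counts["compound_id"].isin(sel_comps)
    return counts, selective


def jaccard_distance(a, b) -> float:
    """JD = 1 - |A & B| / |A | B|; two empty sets have distance 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def client_enrichment(
    hit_map: pd.DataFrame, kinase_annotation: pd.DataFrame
) -> list[EnrichmentResult]:
    """Pairwise HSP90-client-status enrichment among downregulated kinases.

    A kinase is "downregulated" if it scores at least once in the binary
    hit map (row sum > 0).  For each pair of client categories, a 2x2
    table (category x downregulated) is tested with a two-sided Fisher's
    exact test.  Categories with no kinases are skipped.
    """
    ann = kinase_annotation.set_index("kinase_id")["hsp90_status"]
    missing = [k for k in hit_map.index if k not in ann.index]
    if missing:
        raise ValueError(f"kinases without annotation: {missing[:5]}")
    down = hit_map.sum(axis=1) > 0
    results = []
    for cat_a, cat_b in itertools.combinations(HSP90_CATEGORIES, 2):
        in_a = ann.reindex(hit_map.index) == cat_a
        in_b = ann.reindex(hit_map.index) == cat_b
        if not in_a.any() or not in_b.any():
            logger.info("skipping %s vs %s: empty category", cat_a, cat_b)
            continue
        a = int((in_a & down).sum())
        b = int((in_a & ~down).sum())
        c = int((in_b & down).sum())
        d = int((in_b & ~down).sum())
        results.append(_fisher(((a, b), (c, d)), cat_a, cat_b))
    return results


def binding_mode_enrichment(
    hit_compounds: set[str],
    compound_annotation: pd.DataFrame,
    modes: tuple[str, ...] = ("type_I", "type_II", "allosteric"),
) -> list[EnrichmentResult]:
    """Per-mode 2x2 enrichment of binding modes among hit compounds.

    Compounds annotated ``unknown`` are dropped; modes absent from the
    library are skipped.
    """
    ann = compound_annotation[compound_annotation["binding_mode"] != "unknown"]
    is_hit = ann["compound_id"].isin(hit_compounds)
    results = []
    for mode in modes:
        in_mode = ann["binding_mode"] == mode
        if not in_mode.any():
            logger.info("skipping mode %s: absent from library", mode)
            continue
        a = int((in_mode & is_hit).sum())
        b = int((in_mode & ~is_hit).sum())
        c = int((~in_mode & is_hit).sum())
        d = int((~in_mode & ~is_hit).sum())
        results.append(_fisher(((a, b), (c, d)), mode, "hit"))
    return results


def halflife_scoring_correlation(
    half_lives: pd.DataFrame,
    hit_frequency: pd.Series,
    min_n: int = 5,
) -> tuple[float, float]:
    """Spearman rank correlation of reporter half-life vs scoring frequency.

    ``hit_frequency`` is the number of distinct hit compounds per kinase
    line.  Ties get average ranks; the p-value uses the t approximation
    for n > 10 and exact permutation for n <= 10.  Control lines should
    be excluded by the caller.
    """
    hl = half_lives.set_index("cell_line_id")["half_life_h"]
    common = hl.index.intersection(hit_frequency.index)
    if len(common) < min_n:
        raise ValueError(f"need >= {min_n} kinases with both values, got {len(common)}")
    x = hl.loc[common].to_numpy(float)
    y = hit_frequency.loc[common].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector: Spearman correlation undefined")
    n = len(common)
    if n > 10:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rho = float(stats.spearmanr(x, y).statistic)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = float(stats.spearmanr(x, np.asarray(perm)).statistic)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def mutant_wt_comparison(
    hits: pd.DataFrame,
    kinase_annotation: pd.DataFrame,
    half_lives: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per mutant/canonical pair: JD of hit-compound sets, half-life delta."""
    h = hits[hits["hit"]]
    sets = {
        line: set(g.index.get_level_values("compound_id"))
        for line, g in h.groupby("cell_line_id")
    }
    hl = (
        half_lives.set_index("cell_line_id")["half_life_h"]
        if half_lives is not None
        else None
    )
    rows = []
    ann = kinase_annotation
    for _, r in ann[ann["mutant_of"].notna()].iterrows():
        mut, wt = r["kinase_id"], r["mutant_of"]
        if wt not in set(ann["kinase_id"]):
            logger.warning("mutant %s: canonical %s not in panel, skipped", mut, wt)
            continue
        jd = jaccard_distance(sets.get(mut, set()), sets.get(wt, set()))
        d_hl = (
            float(hl.get(mut, np.nan) - hl.get(wt, np.nan)) if hl is not None else np.nan
        )
        rows.append(
            {
                "mutant": mut, "canonical": wt, "jaccard_distance": jd,
                "n_hits_mutant": len(sets.get(mut, ())),
                "n_hits_canonical": len(sets.get(wt, ())),
                "half_life_delta_h": d_hl,
                "activating": bool(r.get("activating", False)),
            }
        )
    return pd.DataFrame(rows)
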