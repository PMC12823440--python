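"""End-to-end orchestration of the screen analysis.

Fixed stage order: normalize -> prescreen -> quality filters -> centering
-> null models -> scheme scores -> hit calling (degradation and
stabilization) -> half-life fits -> atlas statistics.  A run manifest
records the config hash, seed and per-stage row counts so outputs are
traceable and reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import atlas, halflife, normalize, scoring
from .io import PipelineConfig, config_hash

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    poc: pd.DataFrame
    prescreen: pd.DataFrame | None
    tensor: scoring.ScreenTensor
    degradation_scores: pd.DataFrame
    stabilization_scores: pd.DataFrame
    degradation_hits: pd.DataFrame
    stabilization_hits: pd.DataFrame
    hit_matrix: pd.DataFrame
    half_lives: pd.DataFrame
    selectivity: pd.DataFrame
    selective_pairs: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def hit_pairs(self, direction: str = "degradation") -> set[tuple[str, str]]:
        h = self.degradation_hits if direction == "degradation" else self.stabilization_hits
        return set(h.index[h["hit"]])


def run_pipeline(
    raw: pd.DataFrame,
    config: PipelineConfig | None = None,
    *,
    kinase_annotation: pd.DataFrame | None = None,
) -> PipelineResult:
    """Raw luminescence table -> hit map, half-lives and atlas outputs."""
    cfg = config or PipelineConfig()
    manifest = {"config_hash": config_hash(cfg), "seed": cfg.seed, "stages": {}}

    def _stage(name, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %-12s %s", name, counts)

    poc = normalize.normalize_screen(
        raw, cfg.control_compounds,
        apply_intraplate=cfg.apply_intraplate,
        plate_rows=cfg.plate_rows, plate_cols=cfg.plate_cols,
    )
    _stage("normalize", rows=len(poc))

    prescreen = None
    eliminated: set[str] = set()
    if poc["cell_line_id"].isin(cfg.control_lines).any():
        prescreen = normalize.prescreen_compounds(
            poc, cfg.control_lines,
            low=cfg.prescreen_low, high=cfg.prescreen_high,
            max_rel_change=cfg.prescreen_max_rel_change,
            anchor_timepoint=cfg.anchor_timepoint,
            exempt=set(cfg.control_compounds),
        )
        eliminated = set(prescreen.loc[~prescreen["passed"], "compound_id"])
        poc = poc[~poc["compound_id"].isin(eliminated)]
    _stage("prescreen", eliminated=len(eliminated))

    tensor = scoring.build_tensor(
        poc, cfg.timepoints, cfg.control_lines, cfg.control_compounds,
        anchor_timepoint=cfg.anchor_timepoint,
    )
    n_var, zero_frac = scoring.filter_variable_pairs(tensor, cfg.sd_threshold)
    reactive = scoring.filter_reactive_compounds(tensor, cfg.reactive_median_poc)
    _stage("filters", variance_pairs_removed=n_var,
           zero_high_sd_fraction=round(zero_frac, 6), reactive_compounds=len(reactive))

    tensor = scoring.center_series(tensor)
    nulls = scoring.build_null_models(tensor)
    deg_scores = scoring.compute_scheme_scores(tensor, nulls, "degradation", cfg.sigma)
    stab_scores = scoring.compute_scheme_scores(tensor, nulls, "stabilization", cfg.sigma)
    _stage("scores", pairs=len(deg_scores))

    deg_query = scoring.HitQuery(
        "degradation", cfg.degradation_clauses, cfg.degradation_tot
    )
    stab_query = scoring.HitQuery(
        "stabilization", cfg.stabilization_clauses, None
    )
    curated = set(cfg.curated_exclusions)
    deg_hits = scoring.call_hits(
        deg_scores, deg_query, tensor,
        promiscuity_threshold=cfg.promiscuity_threshold,
        exclude_control_line_scorers=cfg.exclude_control_scorers_degradation,
        control_scorer_lines=cfg.control_scorer_lines,
        curated_exclusions=curated,
    )
    stab_hits = scoring.call_hits(
        stab_scores, stab_query, tensor,
        promiscuity_threshold=cfg.promiscuity_threshold,
        control_scorer_lines=cfg.control_scorer_lines,
        curated_exclusions=curated,
    )
    hmat = scoring.hit_matrix(deg_hits, tensor)
    _stage("hits", degradation=int(deg_hits["hit"].sum()),
           stabilization=int(stab_hits["hit"].sum()))

    half_lives = halflife.half_life_table(
        tensor.control_values, cfg.chx_compound, cfg.half_life_cap_h
    )
    _stage("half_life", lines=len(half_lives))

    selectivity, selective_pairs = atlas.selectivity_table(deg_hits)
    _stage("atlas", selective_pairs=len(selective_pairs))

    result = PipelineResult(
        poc=poc, prescreen=prescreen, tensor=tensor,
        degradation_scores=deg_scores, stabilization_scores=stab_scores,
        degradation_hits=deg_hits, stabilization_hits=stab_hits,
        hit_matrix=hmat, half_lives=half_lives,
        selectivity=selectivity, selective_pairs=selective_pairs,
        manifest=manifest,
    )

    if kinase_annotation is not None:
        try:
            result.manifest["client_enrichment"] = [
                e.as_dict() for e in atlas.client_enrichment(hmat, kinase_annotation)
            ]
        except ValueError as err:
            logger.warning("client enrichment skipped: %s", err)
    return result
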