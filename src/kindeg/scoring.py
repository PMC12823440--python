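"""Multitiered hit scoring for the temporal degradation screen.

The screen tensor holds replicate-mean POC values per (cell line,
compound, timepoint).  Scoring proceeds through:

1. replicate-variance filter (pairs with s.d. > 30 POC at *all five*
   timepoints are excluded);
2. reactive-compound filter (median 2-h POC across kinases < 70);
3. two-pass additive centering of the series around 100 POC at the 2-h
   timepoint (first across kinases, then across compounds);
4. eight normalization schemes: z-scores against the DMSO, CHX and NVP-2
   control time series and against the compound population (leave-one-out),
   each timepoint-independent and relative to the 2-h timepoint;
5. integer scheme scores = count of timepoints deviating by >= 2 sigma
   (degradation: decrease; stabilization: increase), +1 for a missing
   timepoint, capped at 5; TOT = sum over schemes;
6. a Boolean hit query over the scores, with promiscuity (> 10 kinase
   lines) and control-line-scorer exclusions;
7. an exhaustive threshold scan minimizing an FDR proxy against planted
   true positives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import CONTROL_COMPOUNDS

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenTensor",
    "NullModels",
    "HitQuery",
    "DEFAULT_DEGRADATION_QUERY",
    "DEFAULT_STABILIZATION_QUERY",
    "DEGRADATION_SCHEMES",
    "STABILIZATION_SCHEMES",
    "build_tensor",
    "filter_variable_pairs",
    "filter_reactive_compounds",
    "center_series",
    "build_null_models",
    "compute_scheme_scores",
    "call_hits",
    "hit_matrix",
    "scan_thresholds",
]

_BASES = ("DMSO", "CHX", "NVP2", "CPD")
DEGRADATION_SCHEMES = tuple(
    f"{b}_norm{v}" for b in _BASES for v in ("", "_2h")
)
STABILIZATION_SCHEMES = tuple(s for s in DEGRADATION_SCHEMES if not s.startswith("CHX"))

SCALE_FLOOR = 1e-6


@dataclass
class ScreenTensor:
    """POC values per (cell line, compound) pair over the timepoint grid.

    ``values``/``rep_sd`` are pair-indexed frames with one column per
    timepoint; ``control_values`` keeps well-level POC of the control
    compounds (the reference samples of the control-basis null models).
    """

    values: pd.DataFrame            # MultiIndex (cell_line_id, compound_id) x timepoints
    rep_sd: pd.DataFrame            # same shape; NaN where < 2 replicates
    control_values: pd.DataFrame    # cell_line_id, compound_id, well_key, timepoint_h, poc
    timepoints: tuple[float, ...]
    kinase_lines: list[str]
    control_lines: list[str]
    control_compounds: dict[str, str]
    exclusions: pd.DataFrame        # pair-indexed bool columns with provenance
    anchor_timepoint: float = 2.0
    centered: bool = False
    anchor_flags: pd.Series | None = None  # True where the 2-h value was missing

    @property
    def library_compounds(self) -> pd.Index:
        comps = self.values.index.get_level_values("compound_id").unique()
        return comps[~comps.isin(self.control_compounds)]

    def pair_anchor(self) -> pd.Series:
        """Per-pair anchor value: the 2-h value, else the earliest available."""
        v = self.values
        anchor = v[self.anchor_timepoint].copy()
        missing = anchor.isna()
        if missing.any():
            backfill = v.loc[missing].bfill(axis=1).iloc[:, 0]
            anchor.loc[missing] = backfill
        return anchor

    def excluded_pairs(self) -> pd.Series:
        if self.exclusions.empty:
            return pd.Series(False, index=self.values.index)
        return self.exclusions.any(axis=1)


def build_tensor(
    poc: pd.DataFrame,
    timepoints=(2.0, 6.0, 10.0, 14.0, 18.0),
    control_lines=("GFP", "dGFP"),
    control_compounds: dict[str, str] | None = None,
    anchor_timepoint: float = 2.0,
) -> ScreenTensor:
    """Aggregate a POC long table into the screen tensor.

    Wells are averaged within a technical replicate, replicates averaged
    into the pair value; the replicate s.d. (ddof=1) feeds the variance
    filter.  Control-compound wells are additionally kept at well level.
    """
    ctrl = dict(CONTROL_COMPOUNDS if control_compounds is None else control_compounds)
    tps = tuple(float(t) for t in timepoints)
    df = poc[poc["timepoint_h"].isin(tps)]

    rep = (
        df.groupby(["cell_line_id", "compound_id", "timepoint_h", "replicate"],
                   sort=False, observed=True)["poc"].mean()
    )
    g = rep.groupby(["cell_line_id", "compound_id", "timepoint_h"], sort=False)
    values = g.mean().unstack("timepoint_h").reindex(columns=list(tps))
    rep_sd = g.std(ddof=1).unstack("timepoint_h").reindex(columns=list(tps))
    values.index.names = ["cell_line_id", "compound_id"]

    ctl = df[df["compound_id"].isin(ctrl)].copy()
    ctl["well_key"] = ctl["plate_id"].astype(str) + ":" + ctl["well"].astype(str)
    control_values = ctl[["cell_line_id", "compound_id", "well_key", "timepoint_h", "poc"]]

    lines = values.index.get_level_values("cell_line_id").unique()
    kinase_lines = [l for l in lines if l not in set(control_lines)]
    exclusions = pd.DataFrame(index=values.index)
    return ScreenTensor(
        values=values, rep_sd=rep_sd, control_values=control_values,
        timepoints=tps, kinase_lines=kinase_lines,
        control_lines=[l for l in lines if l in set(control_lines)],
        control_compounds=ctrl, exclusions=exclusions,
        anchor_timepoint=anchor_timepoint,
    )


def _library_pair_mask(tensor: ScreenTensor, kinase_only: bool = True) -> pd.Series:
    idx = tensor.values.index
    m = ~idx.get_level_values("compound_id").isin(tensor.control_compounds)
    if kinase_only:
        m &= idx.get_level_values("cell_line_id").isin(tensor.kinase_lines)
    return pd.Series(m, index=idx)


def filter_variable_pairs(
    tensor: ScreenTensor, sd_threshold: float = 30.0
) -> tuple[int, float]:
    """Exclude pairs whose replicate s.d. exceeds the threshold at every
    timepoint (strict >).  Returns (number of pairs removed, fraction of
    pairs with zero high-s.d. timepoints); both over kinase x library pairs.
    """
    lib = _library_pair_mask(tensor)
    sd = tensor.rep_sd
    if sd.isna().all(axis=1).any():
        logger.warning("pairs with a single replicate: s.d. undefined, never excluded")
    high = (sd > sd_threshold).fillna(False)
    excluded = high.all(axis=1) & sd.notna().all(axis=1)
    tensor.exclusions["variance_filtered"] = excluded
    n_removed = int((excluded & lib).sum())
    zero_frac = float((high.sum(axis=1)[lib] == 0).mean())
    return n_removed, zero_frac


def filter_reactive_compounds(
    tensor: ScreenTensor,
    median_poc_threshold: float = 70.0,
    min_lines: int = 3,
) -> list[str]:
    """Exclude compounds whose median 2-h POC across kinase lines is < 70.

    Must run on the uncentered tensor (the filter targets genuinely low
    initial signal).  Compounds measured on fewer than ``min_lines``
    kinase lines are not evaluated.
    """
    if tensor.centered:
        raise ValueError("reactive-compound filter must run before centering")
    v = tensor.values[tensor.anchor_timepoint]
    lib = _library_pair_mask(tensor)
    sub = v[lib].dropna()
    med = sub.groupby("compound_id").median()
    n = sub.groupby("compound_id").size()
    evaluable = n >= min_lines
    if (~evaluable).any():
        logger.warning("%d compounds on < %d kinase lines not evaluated",
                       int((~evaluable).sum()), min_lines)
    reactive = sorted(med.index[(med < median_poc_threshold) & evaluable])
    comp_level = tensor.values.index.get_level_values("compound_id")
    tensor.exclusions["reactive_compound"] = comp_level.isin(reactive)
    return reactive


def center_series(tensor: ScreenTensor) -> ScreenTensor:
    """Two-pass additive centering of the pair series around 100 POC.

    Pass 1 shifts every cell line's series by (100 - median over library
    compounds of its 2-h values); pass 2 shifts every library compound's
    series by (100 - median over cell lines of its shifted 2-h values).
    Control compounds receive the per-line shift only: a per-compound
    shift would subtract the genuine decay of the CHX/NVP-2 references.
    Pairs without a 2-h value are anchored at their earliest timepoint.
    """
    v = tensor.values.copy()
    idx = v.index
    anchor = tensor.pair_anchor()
    anchor_flags = tensor.values[tensor.anchor_timepoint].isna() & anchor.notna()

    lib = pd.Series(
        ~idx.get_level_values("compound_id").isin(tensor.control_compounds), index=idx
    )
    lines = idx.get_level_values("cell_line_id")

    shift1 = (100.0 - anchor[lib].groupby("cell_line_id").median()).reindex(
        lines.unique()
    ).fillna(0.0)
    s1 = shift1.reindex(lines).to_numpy()
    v = v.add(s1, axis=0)
    anchor = anchor + s1

    comps = idx.get_level_values("compound_id")
    shift2 = 100.0 - anchor[lib].groupby("compound_id").median()
    s2 = shift2.reindex(comps).fillna(0.0).to_numpy()
    s2 = np.where(lib.to_numpy(), s2, 0.0)  # controls: per-line shift only
    v = v.add(s2, axis=0)

    ctl = tensor.control_values.copy()
    ctl["poc"] = ctl["poc"] + shift1.reindex(ctl["cell_line_id"]).to_numpy()

    return replace(
        tensor, values=v, control_values=ctl, centered=True, anchor_flags=anchor_flags
    )


@dataclass
class NullModels:
    """Reference locations/scales per (basis, variant, cell line, timepoint).

    Control bases (DMSO/CHX/NVP-2) are summarized from well-level control
    values; the CPD basis stores population sums per (line, timepoint) and
    is evaluated leave-one-out.  ``variant`` is ``""`` (timepoint-
    independent) or ``"_2h"`` (on deltas relative to the 2-h timepoint).
    """

    timepoints: tuple[float, ...]
    anchor_timepoint: float
    loc: dict = field(default_factory=dict)    # (basis, variant) -> DataFrame lines x tps
    scale: dict = field(default_factory=dict)
    n_ref: dict = field(default_factory=dict)
    cpd_sums: dict = field(default_factory=dict)  # variant -> (n, s, ss) DataFrames


def _control_reference(ctl: pd.DataFrame, tps, anchor_tp):
    """Per (line, timepoint) mean/sd/count of control wells, plain and delta."""
    wide = ctl.pivot_table(index=["cell_line_id", "well_key"], columns="timepoint_h",
                           values="poc", aggfunc="mean").reindex(columns=list(tps))
    delta = wide.sub(wide[anchor_tp], axis=0)
    out = {}
    for variant, w in (("", wide), ("_2h", delta)):
        g = w.groupby("cell_line_id")
        out[variant] = (g.mean(), g.std(ddof=1), g.count())
    return out


def build_null_models(tensor: ScreenTensor, min_n: int = 3) -> NullModels:
    """Build the eight null models from a centered tensor.

    Control-basis scales with fewer than ``min_n`` reference wells at a
    timepoint fall back to the scale pooled across that line's timepoints;
    zero scales are floored at 1e-6.
    """
    if not tensor.centered:
        logger.warning("building null models on an uncentered tensor")
    nm = NullModels(timepoints=tensor.timepoints, anchor_timepoint=tensor.anchor_timepoint)
    role_of = tensor.control_compounds
    lines = tensor.values.index.get_level_values("cell_line_id").unique()

    for basis in ("DMSO", "CHX", "NVP2"):
        ids = [c for c, r in role_of.items() if r == basis]
        ctl = tensor.control_values[tensor.control_values["compound_id"].isin(ids)]
        if ctl.empty:
            logger.warning("no control wells for basis %s; models unavailable", basis)
            continue
        ref = _control_reference(ctl, tensor.timepoints, tensor.anchor_timepoint)
        for variant, (loc, scale, n) in ref.items():
            loc = loc.reindex(lines)
            scale = scale.reindex(lines)
            n = n.reindex(lines).fillna(0).astype(int)
            pooled = scale.mean(axis=1)
            low_n = n < min_n
            for col in scale.columns:
                scale.loc[low_n[col], col] = pooled[low_n[col]]
            scale = scale.where(scale > SCALE_FLOOR, SCALE_FLOOR).fillna(SCALE_FLOOR)
            nm.loc[(basis, variant)] = loc
            nm.scale[(basis, variant)] = scale
            nm.n_ref[(basis, variant)] = n

    # compound-population sums for leave-one-out evaluation
    lib = _library_pair_mask(tensor, kinase_only=False)
    v = tensor.values[lib.to_numpy()]
    anchor = tensor.pair_anchor()[lib.to_numpy()]
    delta = v.sub(anchor, axis=0)
    for variant, w in (("", v), ("_2h", delta)):
        g = w.groupby("cell_line_id")
        nm.cpd_sums[variant] = (g.count(), g.sum(), (w ** 2).groupby("cell_line_id").sum())
    return nm


def _z_matrices(tensor: ScreenTensor, nulls: NullModels) -> dict[str, np.ndarray]:
    """Per-scheme z-score matrices aligned to tensor.values (pairs x tps)."""
    v = tensor.values
    idx = v.index
    lines = idx.get_level_values("cell_line_id")
    vmat = v.to_numpy()
    anchor = tensor.pair_anchor().to_numpy()
    dmat = vmat - anchor[:, None]
    out = {}
    for basis in ("DMSO", "CHX", "NVP2"):
        for variant, mat in (("", vmat), ("_2h", dmat)):
            key = (basis, variant)
            if key not in nulls.loc:
                continue
            loc = nulls.loc[key].reindex(lines).to_numpy()
            scale = nulls.scale[key].reindex(lines).to_numpy()
            out[f"{basis}_norm{variant}"] = (mat - loc) / scale
    lib = _library_pair_mask(tensor, kinase_only=False).to_numpy()
    for variant, mat in (("", vmat), ("_2h", dmat)):
        n, s, ss = nulls.cpd_sums[variant]
        n_ = n.reindex(lines).to_numpy(dtype=float)
        s_ = s.reindex(lines).to_numpy()
        ss_ = ss.reindex(lines).to_numpy()
        val = np.where(np.isnan(mat), 0.0, mat)
        present = (~np.isnan(mat)).astype(float)
        # leave the evaluated pair out of its own null (library pairs only)
        in_pop = present * lib[:, None]
        n_loo = n_ - in_pop
        s_loo = s_ - val * in_pop
        ss_loo = ss_ - val ** 2 * in_pop
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s_loo / n_loo
            var = (ss_loo - n_loo * mean ** 2) / (n_loo - 1.0)
        var = np.where(n_loo > 1, np.maximum(var, 0.0), np.nan)
        scale = np.sqrt(var)
        scale = np.where(scale > SCALE_FLOOR, scale, SCALE_FLOOR)
        out[f"CPD_norm{variant}"] = (mat - mean) / scale
    return out


def compute_scheme_scores(
    tensor: ScreenTensor,
    nulls: NullModels,
    direction: str = "degradation",
    sigma: float = 2.0,
) -> pd.DataFrame:
    """Integer scheme scores per library pair.

    Counts timepoints with z <= -sigma (degradation) or z >= +sigma
    (stabilization; CHX schemes excluded per the screening design).  A
    pair with any missing timepoint gets +1 on every scheme, capped at 5,
    applied once; TOT is the sum over the direction's schemes.
    """
    if direction not in ("degradation", "stabilization"):
        raise ValueError(direction)
    all_schemes = DEGRADATION_SCHEMES if direction == "degradation" else STABILIZATION_SCHEMES
    z = _z_matrices(tensor, nulls)
    missing_scheme = [s for s in all_schemes if s not in z]
    if missing_scheme:
        logger.warning("control basis missing for schemes %s; they are dropped "
                       "and TOT covers the available schemes", missing_scheme)
    schemes = tuple(s for s in all_schemes if s in z)
    if not schemes:
        raise ValueError("no null models available")
    v = tensor.values
    lib = _library_pair_mask(tensor, kinase_only=False)
    nT = len(tensor.timepoints)
    vm = v.to_numpy()
    n_missing = np.isnan(vm).sum(axis=1)
    fully_missing = n_missing == nT
    has_missing = (n_missing > 0) & ~fully_missing

    cols = {}
    for s in schemes:
        zs = z[s]
        sig = zs <= -sigma if direction == "degradation" else zs >= sigma
        sig = np.where(np.isnan(zs) | np.isnan(vm), False, sig)
        cnt = sig.sum(axis=1).astype(int)
        cnt = np.minimum(cnt + has_missing.astype(int), 5)
        cols[s] = cnt
    scores = pd.DataFrame(cols, index=v.index)
    scores["TOT"] = scores[list(schemes)].sum(axis=1)
    scores["missing_timepoint"] = has_missing
    scores = scores[lib.to_numpy() & ~fully_missing]
    return scores


@dataclass(frozen=True)
class HitQuery:
    """Disjunctive Boolean query over scheme scores.

    A pair is a (raw) hit if any per-scheme clause ``score >= threshold``
    holds, or if ``TOT >= tot_threshold`` (when set).
    """

    direction: str = "degradation"
    clauses: tuple[tuple[str, int], ...] = (
        ("DMSO_norm", 5), ("CHX_norm", 2), ("CPD_norm", 5), ("CHX_norm_2h", 5),
    )
    tot_threshold: int | None = 10

    def evaluate(self, scores: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        hit = pd.Series(False, index=scores.index)
        trig = pd.Series("", index=scores.index, dtype=object)
        for scheme, thr in self.clauses:
            if scheme not in scores.columns:
                raise ValueError(f"query references unknown scheme {scheme!r}")
            m = scores[scheme] >= thr
            hit |= m
            trig[m] = trig[m].where(trig[m] == "", trig[m] + "|") + f"{scheme}>={thr}"
        if self.tot_threshold is not None:
            m = scores["TOT"] >= self.tot_threshold
            hit |= m
            trig[m] = trig[m].where(trig[m] == "", trig[m] + "|") + f"TOT>={self.tot_threshold}"
        return hit, trig


DEFAULT_DEGRADATION_QUERY = HitQuery()
DEFAULT_STABILIZATION_QUERY = HitQuery(
    direction="stabilization",
    clauses=(("DMSO_norm", 5), ("CPD_norm", 5)),
    tot_threshold=None,
)


def call_hits(
    scores: pd.DataFrame,
    query: HitQuery,
    tensor: ScreenTensor,
    *,
    promiscuity_threshold: int = 10,
    exclude_control_line_scorers: bool | None = None,
    control_scorer_lines: tuple[str, ...] = ("GFP",),
    curated_exclusions: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Apply the hit query plus exclusion tiers; returns the hit table.

    Exclusion provenance columns: ``excl_variance``, ``excl_reactive``,
    ``excl_curated``, ``excl_promiscuous``, ``excl_control_scorer``.
    Final hits are restricted to kinase lines; control-line rows are kept
    for provenance with ``hit = False``.
    """
    if exclude_control_line_scorers is None:
        exclude_control_line_scorers = query.direction == "stabilization"
    raw_hit, trig = query.evaluate(scores)
    idx = scores.index
    lines = idx.get_level_values("cell_line_id")
    comps = idx.get_level_values("compound_id")

    excl = tensor.exclusions.reindex(idx).fillna(False)
    ev = excl.get("variance_filtered", pd.Series(False, index=idx)).astype(bool)
    er = excl.get("reactive_compound", pd.Series(False, index=idx)).astype(bool)
    ec = pd.Series(comps.isin(curated_exclusions), index=idx)
    candidate = raw_hit & ~ev & ~er & ~ec

    on_kinase = pd.Series(lines.isin(tensor.kinase_lines), index=idx)
    per_comp = candidate[on_kinase].groupby("compound_id").sum()
    promiscuous = set(per_comp.index[per_comp > promiscuity_threshold])
    ep = pd.Series(comps.isin(promiscuous), index=idx)

    if exclude_control_line_scorers:
        on_ctrl = pd.Series(lines.isin(control_scorer_lines), index=idx)
        scorers = set(comps[(candidate & on_ctrl).to_numpy()])
        eg = pd.Series(comps.isin(scorers), index=idx)
    else:
        eg = pd.Series(False, index=idx)

    hit = candidate & ~ep & ~eg & on_kinase
    out = pd.DataFrame(
        {
            "hit": hit,
            "raw_hit": raw_hit,
            "triggering_clauses": trig.where(raw_hit, ""),
            "excl_variance": ev,
            "excl_reactive": er,
            "excl_curated": ec,
            "excl_promiscuous": ep,
            "excl_control_scorer": eg,
        },
        index=idx,
    )
    out["direction"] = query.direction
    return out


def hit_matrix(hits: pd.DataFrame, tensor: ScreenTensor) -> pd.DataFrame:
    """Binary kinases x compounds matrix of final hits."""
    h = hits["hit"].unstack("compound_id").fillna(False)
    h = h.reindex(tensor.kinase_lines)
    comps = [c for c in h.columns if c not in tensor.control_compounds]
    return h[comps].astype(int)


def scan_thresholds(
    scores: pd.DataFrame,
    reference_pairs: set[tuple[str, str]],
    grid: dict[str, list[int]] | None = None,
    tot_grid: tuple[int, ...] = (8, 10, 12),
    direction: str = "degradation",
    exclude: pd.Series | None = None,
) -> tuple[HitQuery, pd.DataFrame]:
    """Exhaustive threshold scan minimizing the FDR proxy.

    FDR proxy = (hits outside the true-positive reference) / (total hits).
    The winner must recover every reference pair; ties break on fewest
    total hits, then lexicographically smaller thresholds.  If no grid
    point achieves full recall, the best-recall frontier winner is
    returned with a warning.
    """
    if not reference_pairs:
        raise ValueError("reference set must not be empty")
    if grid is None:
        grid = {
            "DMSO_norm": [3, 4, 5],
            "CHX_norm": [1, 2, 3, 4, 5],
            "CPD_norm": [3, 4, 5],
            "CHX_norm_2h": [3, 4, 5],
        }
    idx = scores.index
    if exclude is not None:
        scores = scores[~exclude.reindex(idx).fillna(False)]
        idx = scores.index
    missing_ref = reference_pairs - set(idx)
    if missing_ref:
        raise ValueError(f"reference pairs absent from scores: {sorted(missing_ref)[:5]}")
    is_ref = pd.Series(list(idx.isin(list(reference_pairs))), index=idx).to_numpy()
    n_ref = int(is_ref.sum())

    cols = {s: scores[s].to_numpy() for s in grid}
    tot = scores["TOT"].to_numpy()
    records = []
    best = None
    for combo in itertools.product(*(grid[s] for s in grid)):
        base = np.zeros(len(idx), dtype=bool)
        for s, thr in zip(grid, combo):
            base |= cols[s] >= thr
        for tthr in tot_grid:
            hits = base | (tot >= tthr)
            nh = int(hits.sum())
            tp = int((hits & is_ref).sum())
            fdr = (nh - tp) / nh if nh else 0.0
            recall = tp / n_ref
            records.append((*combo, tthr, nh, tp, recall, fdr))
            key = (-(recall == 1.0), fdr if recall == 1.0 else -recall, nh, combo, tthr)
            if best is None or key < best[0]:
                best = (key, combo, tthr, recall)
    curve = pd.DataFrame(
        records, columns=[*grid, "TOT", "n_hits", "n_true", "recall", "fdr"]
    )
    _, combo, tthr, recall = best
    if recall < 1.0:
        logger.warning("no grid point recovers all reference pairs (best recall %.2f)", recall)
    query = HitQuery(
        direction=direction,
        clauses=tuple(zip(grid, combo)),
        tot_threshold=tthr,
    )
    return query, curve
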