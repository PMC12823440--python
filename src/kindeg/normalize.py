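"""Plate normalization: intraplate correction, POC scaling, prescreen.

Raw luminescence is corrected for smooth intraplate row/column effects by
a median polish on the log signal (estimated from non-control wells and
divided out, preserving the plate median), then rescaled per plate and
timepoint to percent over control (POC):

    POC = 100 * (signal - chir_mean) / (dmso_mean - chir_mean)

where the DMSO (100%) and CHIR-99021 (0%) anchor means are taken over
outlier-trimmed control wells (median +/- 3 x scaled MAD).

The prescreen reproduces the library-assembly filter: on the GFP/dGFP
control lines, a compound concentration fails if any POC < 48, any
POC > 150, or any |POC(t)/POC(2 h) - 1| > 0.58; the verdict prefers the
higher concentration and falls back to the lower one.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CONTROL_COMPOUNDS

logger = logging.getLogger(__name__)

__all__ = [
    "ControlWellSummary",
    "PrescreenVerdict",
    "intraplate_correct",
    "summarize_control_wells",
    "compute_poc",
    "normalize_screen",
    "prescreen_compounds",
    "parse_well",
]

_WELL_RE = re.compile(r"^([A-Z]{1,2})(\d{1,2})$")


def parse_well(label: str) -> tuple[int, int]:
    """Map a well label like ``A01`` or ``AF48`` to 0-based (row, col)."""
    m = _WELL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable well label {label!r}")
    letters, digits = m.groups()
    row = ord(letters[-1]) - ord("A") + (26 if len(letters) == 2 else 0)
    return row, int(digits) - 1


@dataclass
class ControlWellSummary:
    """Trimmed anchor means for one plate and timepoint."""

    plate_id: str
    timepoint_h: float
    dmso_mean: float
    chir_mean: float
    n_dmso_used: int
    n_chir_used: int
    valid: bool = True
    reason: str = ""


@dataclass
class PrescreenVerdict:
    compound_id: str
    passed: bool
    concentration_um: float | None = None
    failure_reasons: dict[float, list[str]] = field(default_factory=dict)


def _trim_mad(values: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Keep values within median +/- n_mad * scaled MAD (MAD * 1.4826)."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = 1.4826 * np.median(np.abs(v - med))
    return v[np.abs(v - med) <= n_mad * mad]


def summarize_control_wells(
    dmso: np.ndarray,
    chir: np.ndarray,
    plate_id: str = "",
    timepoint_h: float = np.nan,
) -> ControlWellSummary:
    """Outlier-trimmed anchor means; invalid if an anchor collapses or inverts."""
    dmso = np.asarray(dmso, float)
    chir = np.asarray(chir, float)
    if len(dmso) < 2 or len(chir) < 2:
        return ControlWellSummary(plate_id, timepoint_h, np.nan, np.nan, 0, 0,
                                  valid=False, reason="too_few_anchor_wells")
    d = _trim_mad(dmso)
    c = _trim_mad(chir)
    if len(d) < 2 or len(c) < 2:
        return ControlWellSummary(plate_id, timepoint_h, np.nan, np.nan, len(d), len(c),
                                  valid=False, reason="anchor_trimmed_out")
    dm, cm = float(np.mean(d)), float(np.mean(c))
    if not dm > cm:
        return ControlWellSummary(plate_id, timepoint_h, dm, cm, len(d), len(c),
                                  valid=False, reason="inverted_anchors")
    return ControlWellSummary(plate_id, timepoint_h, dm, cm, len(d), len(c))


def compute_poc(signal, summary: ControlWellSummary):
    """Percent over control; unclipped, affine in the signal."""
    if not summary.valid:
        raise ValueError(f"invalid control summary for plate {summary.plate_id}")
    return 100.0 * (np.asarray(signal, float) - summary.chir_mean) / (
        summary.dmso_mean - summary.chir_mean
    )


def _median_polish_log(
    mat: np.ndarray, est_mask: np.ndarray, n_iter: int = 2, min_group: int = 6
):
    """Row+column effects of ``log(mat)`` from wells where est_mask is True.

    Rows/columns with fewer than ``min_group`` usable wells contribute no
    effect: a median over a couple of wells would absorb genuine compound
    signal rather than a plate trend.  Effects are taken relative to the
    plate median so a flat plate yields zero effects.
    """
    with np.errstate(divide="ignore"):
        logm = np.log(np.where(mat > 0, mat, np.nan))
    work = np.where(est_mask, logm, np.nan)
    n_row = est_mask.sum(axis=1)
    n_col = est_mask.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols
        work = work - np.nanmedian(work)
        r = np.zeros(mat.shape[0])
        c = np.zeros(mat.shape[1])
        for _ in range(n_iter):
            rm = np.nanmedian(work, axis=1)
            rm = np.where(np.isnan(rm) | (n_row < min_group), 0.0, rm)
            work = work - rm[:, None]
            r += rm
            cm = np.nanmedian(work, axis=0)
            cm = np.where(np.isnan(cm) | (n_col < min_group), 0.0, cm)
            work = work - cm[None, :]
            c += cm
    return logm, r, c


def intraplate_correct(
    values: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    is_control: np.ndarray,
    n_rows: int,
    n_cols: int,
    min_wells: int = 16,
) -> np.ndarray:
    """Divide out a row/column median-polish surface from one plate/timepoint.

    The surface is estimated from non-control wells only; the median signal
    of those wells is preserved.  Plates with fewer than ``min_wells``
    non-control wells are returned unchanged (with a warning).
    """
    values = np.asarray(values, float)
    noncontrol = ~np.asarray(is_control, bool)
    if noncontrol.sum() < min_wells:
        logger.warning("intraplate correction skipped: only %d non-control wells",
                       int(noncontrol.sum()))
        return values.copy()
    mat = np.full((n_rows, n_cols), np.nan)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    mat[rows, cols] = values
    mask[rows, cols] = noncontrol
    logm, r, c = _median_polish_log(mat, mask)
    surface = r[:, None] + c[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        shift = np.nanmedian(logm[mask]) - np.nanmedian((logm - surface)[mask])
    if np.isnan(shift):
        shift = 0.0
    # divide out the surface in linear space so zero wells stay zero
    return values * np.exp(shift - surface[rows, cols])


def normalize_screen(
    raw: pd.DataFrame,
    control_compounds: dict[str, str] | None = None,
    *,
    apply_intraplate: bool = True,
    plate_rows: int = 32,
    plate_cols: int = 48,
) -> pd.DataFrame:
    """Raw luminescence table -> POC long table.

    Per plate and timepoint: optional intraplate correction, anchor-well
    trimmed means, POC rescaling.  Plate/timepoints with an invalid anchor
    summary are dropped with a warning.
    """
    ctrl = dict(CONTROL_COMPOUNDS if control_compounds is None else control_compounds)
    dmso_ids = {c for c, role in ctrl.items() if role == "DMSO"}
    chir_ids = {c for c, role in ctrl.items() if role == "CHIR99021"}
    ctrl_ids = set(ctrl)

    df = raw.copy()
    wells = df["well"].astype(str)
    lut = {w: parse_well(w) for w in wells.unique()}
    rc = np.array([lut[w] for w in wells], dtype=int)
    df["_row"], df["_col"] = rc[:, 0], rc[:, 1]
    df["_is_ctrl_well"] = df["compound_id"].isin(ctrl_ids).to_numpy()

    out_parts = []
    for (plate, tp), g in df.groupby(["plate_id", "timepoint_h"], sort=False):
        sig = g["luminescence"].to_numpy(float)
        if apply_intraplate:
            sig = intraplate_correct(
                sig, g["_row"].to_numpy(), g["_col"].to_numpy(),
                g["_is_ctrl_well"].to_numpy(), plate_rows, plate_cols,
            )
        comp = g["compound_id"].to_numpy()
        summary = summarize_control_wells(
            sig[np.isin(comp, list(dmso_ids))],
            sig[np.isin(comp, list(chir_ids))],
            plate_id=str(plate), timepoint_h=float(tp),
        )
        if not summary.valid:
            logger.warning("plate %s t=%s dropped: %s", plate, tp, summary.reason)
            continue
        part = g[["plate_id", "well", "cell_line_id", "compound_id",
                  "concentration_um", "timepoint_h", "replicate"]].copy()
        part["poc"] = compute_poc(sig, summary)
        out_parts.append(part)
    if not out_parts:
        raise ValueError("no valid plate/timepoint groups in input")
    return pd.concat(out_parts, ignore_index=True)


def prescreen_compounds(
    poc: pd.DataFrame,
    control_lines: tuple[str, ...] = ("GFP", "dGFP"),
    *,
    low: float = 48.0,
    high: float = 150.0,
    max_rel_change: float = 0.58,
    anchor_timepoint: float = 2.0,
    exempt: set[str] | None = None,
) -> pd.DataFrame:
    """Library-assembly filter on control-line trajectories.

    Evaluates every (compound, concentration) over the GFP/dGFP lines; a
    concentration fails on any POC < ``low``, any POC > ``high``, or any
    |POC(t)/POC(2 h) - 1| > ``max_rel_change``.  The verdict uses the
    higher concentration when it passes, otherwise the lower one,
    otherwise the compound is eliminated.  Control compounds are exempt.
    """
    exempt = set(CONTROL_COMPOUNDS) if exempt is None else exempt
    sub = poc[poc["cell_line_id"].isin(control_lines)
              & ~poc["compound_id"].isin(exempt)]
    # replicate/well means per (compound, conc, line, timepoint)
    m = (
        sub.groupby(["compound_id", "concentration_um", "cell_line_id", "timepoint_h"],
                    sort=False)["poc"].mean().reset_index()
    )
    rows = []
    for (cid, conc), g in m.groupby(["compound_id", "concentration_um"], sort=False):
        reasons = set()
        if (g["poc"] < low).any():
            reasons.add("below_48")
        if (g["poc"] > high).any():
            reasons.add("above_150")
        for _, gl in g.groupby("cell_line_id", sort=False):
            a = gl.loc[gl["timepoint_h"] == anchor_timepoint, "poc"]
            if a.empty:
                reasons.add("rel_change_gt_0.58")  # missing 2-h value fails the criterion
                continue
            rel = (gl["poc"] / float(a.iloc[0]) - 1.0).abs()
            if (rel > max_rel_change).any():
                reasons.add("rel_change_gt_0.58")
        rows.append((cid, float(conc), not reasons, sorted(reasons)))
    per_conc = pd.DataFrame(rows, columns=["compound_id", "concentration_um", "conc_pass", "reasons"])

    verdicts = []
    for cid, g in per_conc.groupby("compound_id", sort=False):
        g = g.sort_values("concentration_um", ascending=False)
        chosen = g.loc[g["conc_pass"]]
        if len(chosen):
            verdicts.append((cid, True, float(chosen["concentration_um"].iloc[0]), []))
        else:
            verdicts.append((cid, False, np.nan,
                             sorted({r for rs in g["reasons"] for r in rs})))
    return pd.DataFrame(verdicts,
                        columns=["compound_id", "passed", "concentration_um", "failure_reasons"])
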