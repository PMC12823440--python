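"""Table and configuration I/O for the screen pipeline.

Long/tidy TSV is the interchange format; YAML holds the pipeline
configuration.  Every threshold of the analysis lives on
:class:`PipelineConfig` with the screen's published defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import CONTROL_COMPOUNDS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_screen_table", "write_table", "config_hash"]

RAW_COLUMNS = [
    "plate_id", "well", "cell_line_id", "compound_id",
    "concentration_um", "timepoint_h", "replicate", "luminescence",
]
POC_COLUMNS = [
    "plate_id", "well", "cell_line_id", "compound_id",
    "concentration_um", "timepoint_h", "replicate", "poc",
]


@dataclass
class PipelineConfig:
    """All knobs of the screen analysis, with the assay's default values."""

    timepoints: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0)
    anchor_timepoint: float = 2.0
    # prescreen
    prescreen_low: float = 48.0
    prescreen_high: float = 150.0
    prescreen_max_rel_change: float = 0.58
    # pair/compound quality filters
    sd_threshold: float = 30.0
    reactive_median_poc: float = 70.0
    # scoring
    sigma: float = 2.0
    degradation_clauses: tuple[tuple[str, int], ...] = (
        ("DMSO_norm", 5), ("CHX_norm", 2), ("CPD_norm", 5), ("CHX_norm_2h", 5),
    )
    degradation_tot: int = 10
    stabilization_clauses: tuple[tuple[str, int], ...] = (
        ("DMSO_norm", 5), ("CPD_norm", 5),
    )
    promiscuity_threshold: int = 10
    exclude_control_scorers_degradation: bool = False
    # half-life
    half_life_cap_h: float = 100.0
    # identities
    control_compounds: dict[str, str] = field(
        default_factory=lambda: dict(CONTROL_COMPOUNDS)
    )
    control_lines: tuple[str, ...] = ("GFP", "dGFP")
    control_scorer_lines: tuple[str, ...] = ("GFP",)
    chx_compound: str = "CHX"
    # curation inputs
    curated_exclusions: tuple[str, ...] = ()
    curated_inclusions: tuple[tuple[str, str], ...] = ()  # (cell_line, compound) pairs
    # intraplate correction
    apply_intraplate: bool = True
    plate_rows: int = 32
    plate_cols: int = 48
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat = {}
        for block in ("prescreen", "hit_query", ""):
            src = data.get(block, {}) if block else {
                k: v for k, v in data.items() if not isinstance(v, dict)
            }
            flat.update(src)
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in flat:
                v = flat[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kw[f.name] = v
        return cls(**kw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        prescreen = {k: d.pop(k) for k in list(d) if k.startswith("prescreen_")}
        query = {k: d.pop(k) for k in
                 ("degradation_clauses", "degradation_tot", "stabilization_clauses",
                  "promiscuity_threshold")}
        payload = {"prescreen": prescreen, "hit_query": query, **d}
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(payload), fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_screen_table(path, kind: str = "raw") -> pd.DataFrame:
    """Read a raw or POC measurement table (TSV or CSV, delimiter sniffed).

    Validates the mandatory columns, coerces numerics, preserves unknown
    columns, and logs a row/missing-value report.  Non-numeric values in
    the measurement column raise with the offending row count.
    """
    required = list(RAW_COLUMNS if kind == "raw" else POC_COLUMNS)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    value_col = "luminescence" if kind == "raw" else "poc"
    for col in ("concentration_um", "timepoint_h", value_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"{int(bad.sum())} non-numeric values in column {col!r}")
        df[col] = coerced
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
    logger.info("read %d rows from %s (%d missing %s values)",
                len(df), path, int(df[value_col].isna().sum()), value_col)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)
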