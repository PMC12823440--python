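"""Synthetic temporal luminescence screen generator.

Emulates a kinome-wide reporter screen: a panel of nanoluciferase fusion
cell lines (canonical kinases, mutant kinases, long-lived GFP and
destabilized dGFP controls) dispensed on 1,536-well plates against a
kinase-inhibitor library, read out every 4 h from 2 h to 18 h.  Each
reporter decays with first-order kinetics (rate ``k = ln(2)/half_life``);
compounds perturb that rate through planted effects, and every well is
corrupted by multiplicative log-normal noise plus a smooth per-plate
row/column gradient.  The planted effects are returned as a
:class:`GroundTruth` object so every downstream stage of the pipeline can
be scored against a known answer.

The kinetic model for a well, on the percent-over-control (POC) scale:

* ``inert``                 -- constant 100
* ``translation_shutoff`` / ``transcription_shutoff`` -- ``100 * exp(-k t)``
* ``degrader`` / ``stabilizer`` with rate fold change ``f`` --
  ``100 * (1/f + (1 - 1/f) * exp(-f k t))`` (new steady state ``100/f``)
* ``toxic``                 -- ``100 * exp(-k_tox t)`` on every cell line
* ``positive_control``      -- constant residual signal (CHIR-99021 anchor)

Effect onset is a pure time shift: the effect applies for ``t >= onset``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReporterModel",
    "CompoundEffect",
    "GroundTruth",
    "ScreenConfig",
    "turnover_trajectory",
    "generate_screen",
    "well_label",
    "EFFECT_CLASSES",
    "CONTROL_COMPOUNDS",
]

EFFECT_CLASSES = (
    "inert",
    "degrader",
    "stabilizer",
    "translation_shutoff",
    "transcription_shutoff",
    "toxic",
    "positive_control",
)
_CLASS_CODE = {name: i for i, name in enumerate(EFFECT_CLASSES)}

#: compound id -> control role of the four plate controls
CONTROL_COMPOUNDS = {
    "DMSO": "DMSO",
    "CHIR99021": "CHIR99021",
    "CHX": "CHX",
    "NVP2": "NVP2",
}

_ROW_LETTERS = [chr(ord("A") + i) for i in range(26)] + [
    "A" + chr(ord("A") + i) for i in range(26)
]


def well_label(row: int, col: int) -> str:
    """Plate well label, e.g. ``A01`` ... ``AF48`` on a 32 x 48 plate."""
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


@dataclass(frozen=True)
class ReporterModel:
    """One reporter cell line: a kinase (or GFP/dGFP control) Nluc fusion."""

    cell_line_id: str
    half_life_h: float
    baseline_signal: float
    is_control_line: bool = False
    mutant_of: str | None = None
    activating: bool = False
    hsp90_status: str = "not_defined"

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be positive")
        if self.baseline_signal <= 0:
            raise ValueError("baseline_signal must be positive")


@dataclass(frozen=True)
class CompoundEffect:
    """A planted compound effect on one reporter line.

    ``rate_fold_change`` multiplies the reporter's degradation rate:
    f > 1 is a degrader, f < 1 a stabilizer, f = 1 inert.  Compound-level
    classes (toxic, shutoffs, positive_control) use ``cell_line_id="*"``
    and apply to every line.
    """

    compound_id: str
    cell_line_id: str
    rate_fold_change: float = 1.0
    onset_h: float = 0.0
    class_label: str = "inert"

    def __post_init__(self):
        if self.rate_fold_change <= 0:
            raise ValueError("rate_fold_change must be positive")
        if self.onset_h < 0:
            raise ValueError("onset_h must be non-negative")
        if self.class_label not in EFFECT_CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic screen, the oracle for recovery tests."""

    effects: pd.DataFrame  # compound_id, cell_line_id, class_label, rate_fold_change, onset_h
    reporters: pd.DataFrame  # one row per cell line
    compounds: pd.DataFrame  # one row per compound incl. controls
    seed: int
    config: "ScreenConfig"

    def degrader_pairs(self, min_fold: float = 1.0) -> set[tuple[str, str]]:
        e = self.effects
        m = (e["class_label"] == "degrader") & (e["rate_fold_change"] >= min_fold)
        return set(zip(e.loc[m, "cell_line_id"], e.loc[m, "compound_id"]))

    def protac_pairs(self) -> set[tuple[str, str]]:
        e = self.effects
        prot = set(self.compounds.loc[self.compounds["is_protac"], "compound_id"])
        m = e["compound_id"].isin(prot) & (e["class_label"] == "degrader")
        return set(zip(e.loc[m, "cell_line_id"], e.loc[m, "compound_id"]))

    def kinase_annotation(self) -> pd.DataFrame:
        """Kinase annotation table (HSP90 status, mutant pairing) for the atlas."""
        r = self.reporters.loc[~self.reporters["is_control_line"]]
        out = r.rename(columns={"cell_line_id": "kinase_id"})
        return out[["kinase_id", "hsp90_status", "mutant_of", "activating"]].reset_index(drop=True)

    def compound_annotation(self) -> pd.DataFrame:
        """Compound annotation (binding mode, PROTAC flag) for the atlas."""
        return self.compounds[["compound_id", "role", "is_protac", "binding_mode"]].copy()


@dataclass
class ScreenConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the screened panel: 88 canonical + 10 mutant kinase
    reporters plus GFP/dGFP controls, a ~1,600-compound library (incl. the
    four plate controls and 10 PROTAC true positives), timepoints
    2/6/10/14/18 h and two technical replicates on 1,536-well plates.
    """

    n_kinases: int = 88
    n_mutants: int = 10
    n_compounds: int = 1596  # library compounds incl. PROTACs; + 4 controls = 1600
    n_protacs: int = 10
    timepoints: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0)
    n_replicates: int = 2
    plate_rows: int = 32
    plate_cols: int = 48
    # control wells per plate
    n_dmso_wells: int = 8
    n_chir_wells: int = 8
    n_chx_wells: int = 4
    n_nvp2_wells: int = 4
    # noise model
    noise_sigma: float = 0.05  # log-scale sd of multiplicative well noise
    gradient_amp: float = 0.08  # max fractional row/column plate gradient
    # kinetics
    k_tox: float = 0.1  # per hour, shared toxic decay rate
    # residual POC-scale signal of the CHIR-99021 wells.  0 makes the 0%
    # anchor coincide with complete signal loss, so POC equals the kinetic
    # trajectory exactly (the decay fit's 100*exp(-tau t) form assumes this).
    chir_level: float = 0.0
    half_life_log_median: float = 4.0  # h, log-normal median of kinase half-lives
    half_life_log_sigma: float = 0.7
    # the panel is bracketed by the dGFP (1.1 h) and GFP (30 h) controls;
    # no kinase reporter is shorter-lived than the short-lived control
    half_life_bounds: tuple[float, float] = (1.1, 24.0)
    activating_half_life_factor: float = 0.5
    gfp_half_life: float = 30.0
    dgfp_half_life: float = 1.1
    baseline_median: float = 1e6
    baseline_log_sigma: float = 0.3
    # library composition
    protac_fold_change: float = 12.0
    n_toxic: int = 10
    n_planted_degraders: int = 0
    n_planted_stabilizers: int = 0
    degrader_fold_range: tuple[float, float] = (8.0, 16.0)
    stabilizer_fold_range: tuple[float, float] = (0.15, 0.4)
    client_target_bias: float = 0.7  # P(planted degrader targets an HSP90 client)
    high_conc: float = 10.0
    low_conc: float = 2.5
    extra_effects: list[CompoundEffect] = field(default_factory=list)

    def replace(self, **kw) -> "ScreenConfig":
        return dataclasses.replace(self, **kw)


def turnover_trajectory(
    half_life_h: float,
    rate_fold_change: float,
    class_label: str,
    times,
    *,
    onset_h: float = 0.0,
    k_tox: float = 0.1,
    chir_level: float = 0.0,
) -> np.ndarray:
    """Noiseless reporter trajectory on the POC scale (100 = untreated).

    ``times`` must be sorted and non-negative.  The effect is applied for
    ``t >= onset_h`` as a time shift.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("times must be a sorted, non-negative 1-D sequence")
    if half_life_h <= 0:
        raise ValueError("half_life_h must be positive")
    if rate_fold_change <= 0:
        raise ValueError("rate_fold_change must be positive")
    if class_label not in EFFECT_CLASSES:
        raise ValueError(f"unknown class_label {class_label!r}")
    code = _CLASS_CODE[class_label]
    k = np.log(2.0) / half_life_h
    t_eff = np.maximum(t - onset_h, 0.0)
    return _trajectory_values(
        np.full_like(t, k),
        np.full_like(t, rate_fold_change),
        np.full(t.shape, code, dtype=np.int8),
        t_eff,
        k_tox=k_tox,
        chir_level=chir_level,
    )


def _trajectory_values(k, f, code, t_eff, *, k_tox, chir_level):
    """Vectorized kinetic model; all arguments broadcastable arrays."""
    out = np.full(np.broadcast(k, f, code, t_eff).shape, 100.0)
    decay = np.exp(-k * t_eff)
    m = code == _CLASS_CODE["translation_shutoff"]
    m |= code == _CLASS_CODE["transcription_shutoff"]
    out = np.where(m, 100.0 * decay, out)
    m = (code == _CLASS_CODE["degrader"]) | (code == _CLASS_CODE["stabilizer"])
    with np.errstate(over="ignore"):
        pert = 100.0 * (1.0 / f + (1.0 - 1.0 / f) * np.exp(-f * k * t_eff))
    out = np.where(m, pert, out)
    out = np.where(code == _CLASS_CODE["toxic"], 100.0 * np.exp(-k_tox * t_eff), out)
    out = np.where(code == _CLASS_CODE["positive_control"], chir_level, out)
    return out


# ---------------------------------------------------------------------------
# panel construction


def _build_reporters(cfg: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"KIN{i + 1:03d}" for i in range(cfg.n_kinases)]
    hl = np.exp(
        np.log(cfg.half_life_log_median)
        + cfg.half_life_log_sigma * rng.standard_normal(cfg.n_kinases)
    )
    hl = np.clip(hl, *cfg.half_life_bounds)
    status = rng.choice(
        ["strong", "weak", "non", "not_defined"],
        size=cfg.n_kinases,
        p=[0.2, 0.25, 0.35, 0.2],
    )
    rows = [
        dict(
            cell_line_id=i,
            half_life_h=h,
            is_control_line=False,
            mutant_of=None,
            activating=False,
            hsp90_status=s,
        )
        for i, h, s in zip(ids, hl, status)
    ]
    # mutants pair with distinct canonical kinases; activating mutants are
    # shorter-lived (activity-stability trade-off)
    if cfg.n_mutants > cfg.n_kinases:
        raise ValueError("n_mutants cannot exceed n_kinases")
    parents = rng.choice(cfg.n_kinases, size=cfg.n_mutants, replace=False)
    for j, p in enumerate(parents):
        act = bool(j % 2 == 0)
        h = hl[p] * (cfg.activating_half_life_factor if act else 1.0)
        rows.append(
            dict(
                cell_line_id=f"{ids[p]}mut",
                half_life_h=max(h, cfg.half_life_bounds[0]),
                is_control_line=False,
                mutant_of=ids[p],
                activating=act,
                hsp90_status=status[p],
            )
        )
    rows.append(
        dict(
            cell_line_id="GFP",
            half_life_h=cfg.gfp_half_life,
            is_control_line=True,
            mutant_of=None,
            activating=False,
            hsp90_status="not_defined",
        )
    )
    rows.append(
        dict(
            cell_line_id="dGFP",
            half_life_h=cfg.dgfp_half_life,
            is_control_line=True,
            mutant_of=None,
            activating=False,
            hsp90_status="not_defined",
        )
    )
    df = pd.DataFrame(rows)
    df["baseline_signal"] = cfg.baseline_median * np.exp(
        cfg.baseline_log_sigma * rng.standard_normal(len(df))
    )
    return df


def _build_compounds(cfg: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_lib = cfg.n_compounds - cfg.n_protacs
    if n_lib < 0:
        raise ValueError("n_compounds must be >= n_protacs")
    ids = [f"CPD{i + 1:04d}" for i in range(n_lib)]
    ids += [f"PROTAC{i + 1:02d}" for i in range(cfg.n_protacs)]
    df = pd.DataFrame({"compound_id": ids})
    df["role"] = "library"
    df.loc[df["compound_id"].str.startswith("PROTAC"), "role"] = "protac"
    df["is_protac"] = df["role"] == "protac"
    df["binding_mode"] = rng.choice(
        ["type_I", "type_II", "allosteric", "unknown"],
        size=len(df),
        p=[0.55, 0.2, 0.1, 0.15],
    )
    ctrl = pd.DataFrame(
        {
            "compound_id": list(CONTROL_COMPOUNDS),
            "role": ["control"] * 4,
            "is_protac": False,
            "binding_mode": "unknown",
        }
    )
    return pd.concat([df, ctrl], ignore_index=True)


def _plant_effects(
    cfg: ScreenConfig,
    reporters: pd.DataFrame,
    compounds: pd.DataFrame,
    rng: np.random.Generator,
) -> list[CompoundEffect]:
    effects: list[CompoundEffect] = [
        CompoundEffect("CHX", "*", class_label="translation_shutoff"),
        CompoundEffect("NVP2", "*", class_label="transcription_shutoff"),
        CompoundEffect("CHIR99021", "*", class_label="positive_control"),
    ]
    kin = reporters.loc[~reporters["is_control_line"]]
    kin_ids = list(kin["cell_line_id"])
    client = kin["hsp90_status"].isin(["strong", "weak"]).to_numpy()
    lib = compounds.loc[compounds["role"] == "library", "compound_id"].to_list()
    protacs = compounds.loc[compounds["is_protac"], "compound_id"].to_list()

    # PROTAC true positives: one strong degrader effect on a dedicated target
    if len(protacs) > len(kin_ids):
        raise ValueError("more PROTAC controls than kinase lines to target")
    targets = rng.choice(len(kin_ids), size=len(protacs), replace=False)
    for pid, ti in zip(protacs, targets):
        effects.append(
            CompoundEffect(
                pid, kin_ids[ti], rate_fold_change=cfg.protac_fold_change,
                class_label="degrader",
            )
        )

    free = list(lib)
    rng.shuffle(free)
    n_needed = cfg.n_toxic + cfg.n_planted_degraders + cfg.n_planted_stabilizers
    if n_needed > len(free):
        raise ValueError(
            f"{n_needed} planted compounds requested but only {len(free)} library compounds"
        )
    for _ in range(cfg.n_toxic):
        effects.append(CompoundEffect(free.pop(), "*", class_label="toxic"))

    def _pick_target() -> str:
        if client.any() and rng.random() < cfg.client_target_bias:
            pool = np.flatnonzero(client)
        else:
            pool = np.arange(len(kin_ids))
        return kin_ids[int(rng.choice(pool))]

    lo, hi = cfg.degrader_fold_range
    for _ in range(cfg.n_planted_degraders):
        effects.append(
            CompoundEffect(
                free.pop(), _pick_target(),
                rate_fold_change=float(rng.uniform(lo, hi)),
                class_label="degrader",
            )
        )
    lo, hi = cfg.stabilizer_fold_range
    for _ in range(cfg.n_planted_stabilizers):
        effects.append(
            CompoundEffect(
                free.pop(), _pick_target(),
                rate_fold_change=float(rng.uniform(lo, hi)),
                class_label="stabilizer",
            )
        )
    effects.extend(cfg.extra_effects)
    return effects


# ---------------------------------------------------------------------------
# plate layout


def _layout_template(cfg: ScreenConfig, lib_entries: list[tuple[str, float]]):
    """Assign (compound, concentration) entries plus control wells to plates.

    Returns arrays (plate_index, well_index, compound_idx_in_names, conc)
    with control wells scattered at evenly spaced well indices.
    """
    n_wells = cfg.plate_rows * cfg.plate_cols
    ctrl = (
        [("DMSO", cfg.high_conc)] * cfg.n_dmso_wells
        + [("CHIR99021", cfg.high_conc)] * cfg.n_chir_wells
        + [("CHX", cfg.high_conc)] * cfg.n_chx_wells
        + [("NVP2", cfg.high_conc)] * cfg.n_nvp2_wells
    )
    n_ctrl = len(ctrl)
    cap = n_wells - n_ctrl
    if cap <= 0:
        raise ValueError("plate too small for the configured control wells")
    plates, wells, comps, concs = [], [], [], []
    ctrl_pos = np.linspace(0, n_wells - 1, n_ctrl).astype(int) if n_ctrl else np.array([], int)
    for p_idx, start in enumerate(range(0, len(lib_entries), cap)):
        chunk = lib_entries[start : start + cap]
        lib_pos = np.setdiff1d(np.arange(n_wells), ctrl_pos)[: len(chunk)]
        for (cid, conc), w in zip(ctrl, ctrl_pos):
            plates.append(p_idx), wells.append(int(w)), comps.append(cid), concs.append(conc)
        for (cid, conc), w in zip(chunk, lib_pos):
            plates.append(p_idx), wells.append(int(w)), comps.append(cid), concs.append(conc)
    return (
        np.array(plates, dtype=np.int32),
        np.array(wells, dtype=np.int32),
        np.array(comps, dtype=object),
        np.array(concs, dtype=float),
    )


def generate_screen(config: ScreenConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a raw long-format luminescence screen plus its ground truth.

    Deterministic for a given ``(config, seed)``.  Control-line (GFP/dGFP)
    plates carry every library compound at both the high and the low
    concentration, emulating the two-concentration prescreen; kinase-line
    plates carry the high concentration only.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    reporters = _build_reporters(config, rng)
    compounds = _build_compounds(config, rng)
    effects = _plant_effects(config, reporters, compounds, rng)

    lib = compounds.loc[compounds["role"] != "control", "compound_id"].to_list()
    kin_entries = [(c, config.high_conc) for c in lib]
    ctl_entries = kin_entries + [(c, config.low_conc) for c in lib]
    templ_kin = _layout_template(config, kin_entries)
    templ_ctl = _layout_template(config, ctl_entries)

    comp_names = list(compounds["compound_id"])
    comp_idx = {c: i for i, c in enumerate(comp_names)}
    line_names = list(reporters["cell_line_id"])
    n_lines, n_comp = len(line_names), len(comp_names)

    # per-(line, compound) effect lookups
    k_line = (np.log(2.0) / reporters["half_life_h"].to_numpy()).astype(float)
    cls2d = np.zeros((n_lines, n_comp), dtype=np.int8)
    f2d = np.ones((n_lines, n_comp))
    on2d = np.zeros((n_lines, n_comp))
    eff_rows = []
    for e in effects:
        ci = comp_idx[e.compound_id]
        code = _CLASS_CODE[e.class_label]
        if e.cell_line_id == "*":
            cls2d[:, ci] = code
            f2d[:, ci] = e.rate_fold_change
            on2d[:, ci] = e.onset_h
            eff_rows.append((e.compound_id, "*", e.class_label, e.rate_fold_change, e.onset_h))
        else:
            li = line_names.index(e.cell_line_id)
            cls2d[li, ci] = code
            f2d[li, ci] = e.rate_fold_change
            on2d[li, ci] = e.onset_h
            eff_rows.append((e.compound_id, e.cell_line_id, e.class_label, e.rate_fold_change, e.onset_h))

    well_names = np.array(
        [well_label(w // config.plate_cols, w % config.plate_cols)
         for w in range(config.plate_rows * config.plate_cols)],
        dtype=object,
    )

    # assemble the well table: one row per (line, replicate, well)
    blocks = []
    is_ctl_line = reporters["is_control_line"].to_numpy()
    for li, line in enumerate(line_names):
        plates, wells, comps, concs = templ_ctl if is_ctl_line[li] else templ_kin
        ci = np.array([comp_idx[c] for c in comps], dtype=np.int32)
        for rep in range(1, config.n_replicates + 1):
            blocks.append((li, rep, plates, wells, ci, concs))

    li_arr = np.concatenate([np.full(len(b[2]), b[0], dtype=np.int32) for b in blocks])
    rep_arr = np.concatenate([np.full(len(b[2]), b[1], dtype=np.int16) for b in blocks])
    plate_arr = np.concatenate([b[2] for b in blocks])
    well_arr = np.concatenate([b[3] for b in blocks])
    ci_arr = np.concatenate([b[4] for b in blocks])
    conc_arr = np.concatenate([b[5] for b in blocks])
    n_well_rows = len(li_arr)

    # plate-instance ids and gradients
    inst_key = (li_arr.astype(np.int64) * config.n_replicates + (rep_arr - 1)) * 16 + plate_arr
    uniq, inst_idx = np.unique(inst_key, return_inverse=True)
    grad_r = rng.uniform(-config.gradient_amp, config.gradient_amp, size=len(uniq))
    grad_c = rng.uniform(-config.gradient_amp, config.gradient_amp, size=len(uniq))
    rpos = (well_arr // config.plate_cols) / max(config.plate_rows - 1, 1) - 0.5
    cpos = (well_arr % config.plate_cols) / max(config.plate_cols - 1, 1) - 0.5
    grad = (1.0 + grad_r[inst_idx] * rpos) * (1.0 + grad_c[inst_idx] * cpos)

    k_arr = k_line[li_arr]
    cls_arr = cls2d[li_arr, ci_arr]
    f_arr = f2d[li_arr, ci_arr]
    on_arr = on2d[li_arr, ci_arr]
    base_arr = reporters["baseline_signal"].to_numpy()[li_arr]

    tps = np.asarray(config.timepoints, dtype=float)
    vals = np.empty((len(tps), n_well_rows))
    for ti, t in enumerate(tps):
        t_eff = np.maximum(t - on_arr, 0.0)
        traj = _trajectory_values(
            k_arr, f_arr, cls_arr, t_eff, k_tox=config.k_tox, chir_level=config.chir_level
        )
        noise = (
            np.exp(rng.normal(0.0, config.noise_sigma, size=n_well_rows))
            if config.noise_sigma > 0
            else 1.0
        )
        vals[ti] = base_arr * traj / 100.0 * noise * grad

    line_s = pd.Series(np.array(line_names, dtype=object)[li_arr])
    plate_id = (
        line_s
        + "_r" + pd.Series(rep_arr).astype(str)
        + "_p" + pd.Series(plate_arr + 1).astype(str)
    ).to_numpy(dtype=object)

    nt = len(tps)
    raw = pd.DataFrame(
        {
            "plate_id": np.tile(plate_id, nt),
            "well": np.tile(well_names[well_arr], nt),
            "cell_line_id": np.tile(line_s.to_numpy(dtype=object), nt),
            "compound_id": np.tile(np.array(comp_names, dtype=object)[ci_arr], nt),
            "concentration_um": np.tile(conc_arr, nt),
            "timepoint_h": np.repeat(tps, n_well_rows),
            "replicate": np.tile(rep_arr, nt),
            "luminescence": vals.reshape(-1),
        }
    )

    truth = GroundTruth(
        effects=pd.DataFrame(
            eff_rows,
            columns=["compound_id", "cell_line_id", "class_label", "rate_fold_change", "onset_h"],
        ),
        reporters=reporters,
        compounds=compounds,
        seed=seed,
        config=config,
    )
    return raw, truth
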