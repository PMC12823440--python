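import numpy as np
import pandas as pd
import pytest

from kindeg import simulate as sim
from kindeg.io import PipelineConfig
from kindeg.pipeline import run_pipeline
from kindeg import scoring


TINY = dict(n_kinases=8, n_mutants=2, n_compounds=40, n_protacs=2, n_toxic=2)


@pytest.fixture(scope="session")
def tiny_noiseless():
    """Small noiseless screen with 2 PROTACs and 2 toxic compounds."""
    cfg = sim.ScreenConfig(noise_sigma=0.0, gradient_amp=0.0, **TINY)
    raw, truth = sim.generate_screen(cfg, seed=11)
    return raw, truth


@pytest.fixture(scope="session")
def tiny_result(tiny_noiseless):
    raw, truth = tiny_noiseless
    return run_pipeline(raw, PipelineConfig()), truth


@pytest.fixture(scope="session")
def tiny_noisy():
    """Small screen with default noise, planted degraders and stabilizers."""
    cfg = sim.ScreenConfig(
        n_planted_degraders=6, n_planted_stabilizers=4, **TINY
    )
    raw, truth = sim.generate_screen(cfg, seed=23)
    return raw, truth


@pytest.fixture(scope="session")
def tiny_noisy_result(tiny_noisy):
    raw, truth = tiny_noisy
    return run_pipeline(raw, PipelineConfig()), truth


def make_tensor(
    pair_values: dict,
    pair_sds: dict | None = None,
    control_wells: dict | None = None,
    timepoints=(2.0, 6.0, 10.0, 14.0, 18.0),
    control_lines=("GFP", "dGFP"),
    centered=True,
):
    """Hand-build a ScreenTensor.

    ``pair_values[(line, compound)]`` is the 5-vector of replicate-mean POC
    (NaN allowed); ``pair_sds`` optional replicate s.d. vectors;
    ``control_wells[(line, control_compound)]`` is a list of per-well
    trajectories for the null-model references.
    """
    pair_sds = pair_sds or {}
    control_wells = control_wells or {}
    rows = []
    for (line, comp), vals in pair_values.items():
        sds = pair_sds.get((line, comp), [0.0] * len(timepoints))
        for t, v, s in zip(timepoints, vals, sds):
            if np.isnan(v):
                continue
            d = s / np.sqrt(2.0)
            for rep, val in ((1, v + d), (2, v - d)):
                rows.append(
                    dict(plate_id=f"{line}_p1", well="A01", cell_line_id=line,
                         compound_id=comp, concentration_um=10.0,
                         timepoint_h=t, replicate=rep, poc=val)
                )
    for (line, comp), wells in control_wells.items():
        for wi, traj in enumerate(wells):
            for t, v in zip(timepoints, traj):
                rows.append(
                    dict(plate_id=f"{line}_p1", well=f"B{wi + 1:02d}",
                         cell_line_id=line, compound_id=comp,
                         concentration_um=10.0, timepoint_h=t, replicate=1, poc=v)
                )
    poc = pd.DataFrame(rows)
    tensor = scoring.build_tensor(poc, timepoints, control_lines)
    tensor.centered = centered
    return tensor


@pytest.fixture
def tensor_factory():
    return make_tensor
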