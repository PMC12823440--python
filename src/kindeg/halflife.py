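"""Reporter half-life fitting from CHX (translation-shutoff) trajectories.

Under cycloheximide the reporter can no longer be synthesized, so its POC
trajectory follows pure first-order decay, ``POC(t) = 100 * exp(-tau t)``.
The amplitude is fixed at 100 (the trajectories are centered POC), tau is
constrained non-negative, and half-lives longer than the cap (default
100 h) are reported as censored: an 18-h assay window cannot resolve them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = ["DecayFit", "fit_decay", "half_life_table"]

HALF_LIFE_CAP_H = 100.0


@dataclass
class DecayFit:
    cell_line_id: str
    tau: float                 # decay rate, per hour
    half_life_h: float
    rss: float
    converged: bool
    censored: bool             # half-life reported at the cap

    def as_dict(self):
        return {
            "cell_line_id": self.cell_line_id,
            "tau_per_h": self.tau,
            "half_life_h": self.half_life_h,
            "rss": self.rss,
            "converged": self.converged,
            "censored": self.censored,
        }


def _model(t, tau):
    return 100.0 * np.exp(-tau * t)


def fit_decay(
    times,
    values,
    cell_line_id: str = "",
    cap_h: float = HALF_LIFE_CAP_H,
) -> DecayFit:
    """Nonlinear least squares of ``100 * exp(-tau t)`` with tau >= 0.

    The initial guess comes from a log-linear regression on the values
    clipped to (0, 100].  Requires >= 3 timepoints with non-negative
    times; order and duplicated timepoints do not matter.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    tau_min = np.log(2.0) / cap_h

    if np.all(y >= 100.0):
        rss = float(np.sum((y - 100.0) ** 2))
        return DecayFit(cell_line_id, 0.0, cap_h, rss, True, True)

    yc = np.clip(y, 1e-9, 100.0)
    slope = np.polyfit(t, np.log(yc / 100.0), 1)[0]
    tau0 = max(-slope, tau_min)
    try:
        popt, _ = curve_fit(
            _model, t, y, p0=[tau0], bounds=(0.0, np.inf), maxfev=10000
        )
        tau = float(popt[0])
        converged = True
    except RuntimeError:
        tau, converged = tau0, False
        logger.warning("decay fit did not converge for %s", cell_line_id or "<series>")
    rss = float(np.sum((y - _model(t, tau)) ** 2))
    if tau < tau_min:
        return DecayFit(cell_line_id, tau, cap_h, rss, converged, True)
    return DecayFit(cell_line_id, tau, np.log(2.0) / tau, rss, converged, False)


def half_life_table(
    poc: pd.DataFrame,
    chx_compound: str = "CHX",
    cap_h: float = HALF_LIFE_CAP_H,
) -> pd.DataFrame:
    """One decay fit per cell line from its CHX trajectory.

    ``poc`` is a long table with cell_line_id / compound_id / timepoint_h /
    poc columns (wells and replicates are averaged before fitting).  Lines
    without CHX data are skipped with a warning.
    """
    sub = poc[poc["compound_id"] == chx_compound]
    if sub.empty:
        raise ValueError(f"no rows for CHX compound {chx_compound!r}")
    rows = []
    for line, g in sub.groupby("cell_line_id", sort=False):
        traj = g.groupby("timepoint_h")["poc"].mean()
        if len(traj) < 3:
            logger.warning("skipping %s: only %d CHX timepoints", line, len(traj))
            continue
        rows.append(fit_decay(traj.index, traj.to_numpy(), str(line), cap_h).as_dict())
    return pd.DataFrame(rows)
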