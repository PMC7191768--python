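"""Growth-rate estimation and the strain-level association analysis.

The maximum specific growth rate mu (natural-log units per hour) is the
steepest sliding-window slope of ln(OD600) vs time.  Per-strain summaries
(replication slope, S10 dosage, ori/ter ratio, S10 position, mu) feed a
Pearson correlation matrix linking replication dynamics to locus position
and growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MuEstimate",
    "StrainSummary",
    "estimate_mu",
    "normalize_mu",
    "strain_association",
]

DETECTION_FLOOR_OD = 0.02
DEFAULT_WINDOW_POINTS = 8  # 40 min at 5-min sampling


@dataclass(frozen=True)
class MuEstimate:
    mu_per_h: float
    window: tuple[float, float]  # time span (min) of the steepest window
    r2: float


@dataclass(frozen=True)
class StrainSummary:
    strain_id: str
    s10_position_kb: float
    s10_dosage: float
    ori_ter_ratio: float
    mean_slope: float
    mu_per_h: float


def estimate_mu(
    curve: pd.DataFrame,
    window_points: int = DEFAULT_WINDOW_POINTS,
    floor_od: float = DETECTION_FLOOR_OD,
) -> MuEstimate:
    """Maximum-slope sliding-window fit of ln(OD) vs time.

    Readings at or below ``floor_od`` are excluded (below-detection noise);
    the slope of the steepest window is converted from per-minute to per-hour.
    Invariant to multiplying all OD values by a positive constant (up to the
    floor), since scaling only shifts ln(OD) by a constant.
    """
    t = curve["time_min"].to_numpy(dtype=float)
    od = curve["od600"].to_numpy(dtype=float)
    keep = od > floor_od
    t, od = t[keep], od[keep]
    if len(t) < window_points:
        raise ValueError(
            f"only {len(t)} readings above the detection floor, need {window_points}"
        )
    y = np.log(od)
    best = None
    for i in range(len(t) - window_points + 1):
        sl = slice(i, i + window_points)
        fit = stats.linregress(t[sl], y[sl])
        if best is None or fit.slope > best[0]:
            best = (fit.slope, fit.rvalue**2, t[sl][0], t[sl][-1])
    slope, r2, t0, t1 = best
    return MuEstimate(mu_per_h=float(slope * 60.0), window=(float(t0), float(t1)), r2=float(r2))


def normalize_mu(movant: MuEstimate, parental: MuEstimate) -> float:
    """Movant growth rate as a percentage of the parental rate."""
    if parental.mu_per_h <= 0:
        raise ValueError("parental mu must be positive")
    return 100.0 * movant.mu_per_h / parental.mu_per_h


def strain_association(table: pd.DataFrame) -> pd.DataFrame:
    """Correlations of the replication slope with position, dosage, ori/ter and mu.

    ``table`` has one row per strain with columns s10_position_kb,
    s10_dosage, ori_ter_ratio, mean_slope, mu_per_h.  Returns a frame with
    one row per (slope, variable) pair: Pearson r and two-sided p from the
    t distribution with n-2 df.
    """
    needed = ["s10_position_kb", "s10_dosage", "ori_ter_ratio", "mean_slope", "mu_per_h"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table) < 4:
        raise ValueError("need at least 4 strains")
    slope = table["mean_slope"].to_numpy(dtype=float)
    rows = []
    for var in ["s10_position_kb", "s10_dosage", "ori_ter_ratio", "mu_per_h"]:
        x = table[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant column: {var}")
        if np.std(slope) == 0:
            raise ValueError("constant column: mean_slope")
        r, p = stats.pearsonr(slope, x)
        rows.append({"variable": var, "r": float(r), "p": float(p), "n": len(table)})
    return pd.DataFrame(rows)
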