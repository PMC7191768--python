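"""FRAP trace analysis.

Two assays share the machinery: whole-cell bleaching followed for minutes
reports protein re-synthesis (percent recovery after imaging-decay
correction against unbleached neighbour cells), and partial-cytoplasm
bleaching at high frame rate reports cytoplasmic mobility through the
recovery half-time tau of a single-exponential fit

    F(t) = F_inf - (F_inf - F_bleach) * 2**(-t / tau_half)

so the signal reaches halfway to its plateau at t = tau_half.  Fits are
accepted when R^2 > 0.8 and the cell is shorter than 6 um; populations are
compared with Kruskal-Wallis plus Dunn's post-hoc tests against a control
group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrichment import bh_adjust

__all__ = [
    "TauEstimate",
    "correct_imaging_decay",
    "percent_recovery",
    "fit_recovery",
    "population_stats",
    "compare_groups",
]

R2_ACCEPT = 0.8
MAX_CELL_LENGTH_UM = 6.0


@dataclass(frozen=True)
class TauEstimate:
    tau_half: float
    F_bleach: float
    F_inf: float
    r2: float
    cell_length_um: float
    accepted: bool
    immobile_fraction: float = np.nan
    reason: str = ""


def _trace_arrays(trace: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = trace["time_ms"].to_numpy(dtype=float)
    f = trace["fluorescence"].to_numpy(dtype=float)
    pre = (
        trace["pre_bleach"].to_numpy(dtype=bool)
        if "pre_bleach" in trace
        else t < 0
    )
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    return t, f, pre


def correct_imaging_decay(
    bleached: pd.DataFrame, controls: list[pd.DataFrame], tol_frames: float = 0.5
) -> pd.DataFrame:
    """Remove shared imaging decay using unbleached neighbour cells.

    Subtracts the controls' mean drift relative to their own first frame:
    ``corrected(t) = bleached(t) - (mean_controls(t) - mean_controls(t0))``,
    preserving the bleached cell's baseline.  Control frames must align with
    the bleached trace within half a frame interval.
    """
    if not controls:
        raise ValueError("need at least one unbleached control trace")
    t, f, pre = _trace_arrays(bleached)
    dt = np.median(np.diff(t))
    ctrl = np.zeros_like(f)
    for c in controls:
        tc, fc, _ = _trace_arrays(c)
        idx = np.searchsorted(tc, t)
        idx = np.clip(idx, 0, len(tc) - 1)
        left = np.clip(idx - 1, 0, len(tc) - 1)
        use_left = np.abs(tc[left] - t) < np.abs(tc[idx] - t)
        nearest = np.where(use_left, left, idx)
        if np.any(np.abs(tc[nearest] - t) > tol_frames * dt):
            raise ValueError("control trace time base does not align with bleached trace")
        ctrl += fc[nearest]
    ctrl /= len(controls)
    out = bleached.copy()
    out["fluorescence"] = f - (ctrl - ctrl[0])
    return out


def percent_recovery(
    trace: pd.DataFrame,
    t_end: float | None = None,
) -> float:
    """Percent of the bleached signal recovered by the end of the trace.

    ``100 * (F(t_end) - F(t_post)) / (F(t_pre) - F(t_post))`` where F(t_pre)
    is the mean of the pre-bleach frames, F(t_post) the first post-bleach
    frame, and t_end defaults to the last frame.
    """
    t, f, pre = _trace_arrays(trace)
    if not pre.any():
        raise ValueError("trace has no pre-bleach frames")
    f_pre = f[pre].mean()
    post_t, post_f = t[~pre], f[~pre]
    f_post = post_f[0]
    if f_pre <= f_post:
        raise ValueError("degenerate bleach: pre-bleach signal not above post-bleach")
    if t_end is None:
        f_end = post_f[-1]
    else:
        f_end = post_f[np.argmin(np.abs(post_t - t_end))]
    return 100.0 * (f_end - f_post) / (f_pre - f_post)


def fit_recovery(
    trace: pd.DataFrame, cell_length_um: float | None = None
) -> TauEstimate:
    """Nonlinear least-squares fit of the single-exponential recovery model.

    Fits the post-bleach portion only.  Non-convergent or degenerate fits
    return a flagged, unaccepted estimate rather than raising.  Acceptance
    requires R^2 > 0.8 and cell length < 6 um.
    """
    t, f, pre = _trace_arrays(trace)
    t_post = t[~pre]
    f_post = f[~pre]
    if len(t_post) < 10:
        raise ValueError("need at least 10 post-bleach frames")
    if cell_length_um is None:
        cell_length_um = (
            float(trace["cell_length_um"].iloc[0])
            if "cell_length_um" in trace
            else np.nan
        )
    t0 = t_post[0]
    tt = t_post - t0

    def model(x, f_inf, f_bleach, tau):
        return f_inf - (f_inf - f_bleach) * 2.0 ** (-x / tau)

    span = max(f_post.max() - f_post.min(), 1e-12)
    p0 = (f_post[-5:].mean(), f_post[0], max(tt[-1] / 5.0, tt[1] - tt[0]))
    try:
        popt, _ = optimize.curve_fit(
            model, tt, f_post, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
        f_inf, f_bleach, tau = map(float, popt)
        resid = f_post - model(tt, *popt)
        ss_tot = float(np.sum((f_post - f_post.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        reason = ""
    except RuntimeError:
        f_inf, f_bleach, tau, r2 = np.nan, np.nan, np.nan, 0.0
        reason = "fit did not converge"

    accepted = (r2 > R2_ACCEPT) and not np.isnan(tau)
    if accepted and not np.isnan(cell_length_um) and cell_length_um >= MAX_CELL_LENGTH_UM:
        accepted = False
        reason = f"cell length {cell_length_um} um >= {MAX_CELL_LENGTH_UM} um"
    elif not accepted and not reason:
        reason = f"R^2 {r2:.3f} <= {R2_ACCEPT}"

    if pre.any() and not np.isnan(tau):
        f_pre = f[pre].mean()
        denom = f_pre - f_bleach
        immobile = 1.0 - (f_inf - f_bleach) / denom if denom > 0 else np.nan
    else:
        immobile = np.nan
    return TauEstimate(
        tau_half=tau, F_bleach=f_bleach, F_inf=f_inf, r2=r2,
        cell_length_um=cell_length_um, accepted=accepted,
        immobile_fraction=immobile, reason=reason,
    )


def population_stats(taus) -> dict:
    """Mean, median, t-based 95% CI of the mean, and n for accepted half-times."""
    x = np.asarray(list(taus), dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 estimates")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "ci95": (mean - half, mean + half),
        "n": n,
    }


def compare_groups(
    groups: dict[str, np.ndarray], control: str | None = None
) -> dict:
    """Kruskal-Wallis across groups plus Dunn's pairwise post-hoc tests.

    Dunn's z uses the tie-corrected rank variance; pairwise p-values are
    two-sided normal and BH-adjusted.  When ``control`` is given only
    control-vs-other pairs are tested, mirroring comparisons against a
    parental strain.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 values each")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0, "pairwise": {}}
    H, p = stats.kruskal(*samples)

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    sizes = [len(s) for s in samples]
    mean_ranks = {}
    start = 0
    for g, sz in zip(names, sizes):
        mean_ranks[g] = ranks[start : start + sz].mean()
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    if control is not None:
        pairs = [(control, g) for g in names if g != control]
    else:
        pairs = list(combinations(names, 2))
    zvals, pvals = [], []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zvals.append(z)
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    padj = bh_adjust(pvals) if pairs else np.array([])
    pairwise = {
        pair: {"z": float(z), "p": float(pv), "padj": float(pa)}
        for pair, z, pv, pa in zip(pairs, zvals, pvals, padj)
    }
    return {"H": float(H), "p": float(p), "pairwise": pairwise}
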