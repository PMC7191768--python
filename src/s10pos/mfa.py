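"""Marker frequency analysis (MFA).

Read coverage of exponentially growing cells, normalised window-by-window to
a non-replicating (stationary-phase) control, falls off log-linearly from
the origin to the terminus of each replichore.  This module normalises
coverage tracks, lays the chromosome out on a ter-ori-ter axis, fits the
per-replichore log2 slope (log2 frequency change per kb), and computes
zone-averaged ratios: ori/ter and the dosage of annotated loci such as the
S10 ribosomal-protein cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout

__all__ = [
    "CoverageTrack",
    "MarkerFrequencyProfile",
    "MfaResult",
    "normalize_to_control",
    "to_ter_ori_ter",
    "fit_replichore_slope",
    "zone_ratio",
    "locus_dosage",
    "estimate_C_over_tau",
    "analyze_profile",
]

R2_QC_THRESHOLD = 0.95  # accepted replichore fits have R^2 above this
DEFAULT_ZONE_WINDOWS = 50


@dataclass(frozen=True)
class CoverageTrack:
    """Windowed read counts tiling one replicon."""

    replicon: str
    window_bp: int
    window_starts: np.ndarray  # 0-based half-open starts, in order
    counts: np.ndarray  # non-negative per-window read counts
    mask: np.ndarray | None = None  # True = excluded (repeats / zero control)

    def __post_init__(self) -> None:
        starts = np.asarray(self.window_starts)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "window_starts", starts)
        object.__setattr__(self, "counts", counts)
        if starts.shape != counts.shape:
            raise ValueError("window_starts and counts must have equal length")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(starts) != self.window_bp):
            raise ValueError("windows must tile the replicon in order")
        mask = (
            np.zeros(starts.shape, dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        object.__setattr__(self, "mask", mask)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def to_bedgraph(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.replicon,
                "start": self.window_starts,
                "end": self.window_starts + self.window_bp,
                "value": self.counts.astype(int),
            }
        ).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class MarkerFrequencyProfile:
    """Per-window log2 control-normalised frequency along one replicon.

    ``axis_kb`` is the plotting coordinate: genomic before reordering,
    ter-ori-ter (origin at the midpoint) after :func:`to_ter_ori_ter`.
    ``genomic_start`` keeps each window's original coordinate so the
    reordering stays a bijection.
    """

    replicon: str
    window_bp: int
    axis_kb: np.ndarray
    log2_freq: np.ndarray
    mask: np.ndarray
    genomic_start: np.ndarray
    ter_ori_ter: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.axis_kb)

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.mask
        return self.axis_kb[keep], self.log2_freq[keep]


@dataclass(frozen=True)
class MfaResult:
    slope_left: float
    slope_right: float
    intercept_left: float
    intercept_right: float
    r2_left: float
    r2_right: float
    mean_slope: float
    ori_freq: float
    ter_freq: float
    ori_ter_ratio: float
    locus_dosages: dict = field(default_factory=dict)
    qc_flags: tuple = ()


def normalize_to_control(
    sample: CoverageTrack,
    control: CoverageTrack,
    sample_total: float | None = None,
    control_total: float | None = None,
) -> MarkerFrequencyProfile:
    """log2 of total-normalised sample over total-normalised control.

    Windows where either track has zero counts are masked, never imputed
    (mirrors dropping repeated/unmappable sequence rather than smoothing).
    For a multi-replicon genome pass the genome-wide read totals as
    ``sample_total`` / ``control_total`` so frequencies are comparable
    across replicons; they default to the track's own totals.
    """
    if sample.replicon != control.replicon or sample.window_bp != control.window_bp:
        raise ValueError("sample and control are on different window grids")
    if sample.n_windows != control.n_windows or np.any(
        sample.window_starts != control.window_starts
    ):
        raise ValueError("sample and control window grids are not aligned")
    if control.counts.sum() == 0:
        raise ValueError("control track is all zero")
    if sample.counts.sum() == 0:
        raise ValueError("sample track is all zero")
    mask = sample.mask | control.mask | (sample.counts == 0) | (control.counts == 0)
    s = sample.counts / (sample_total if sample_total else sample.counts.sum())
    c = control.counts / (control_total if control_total else control.counts.sum())
    log2f = np.full(sample.n_windows, np.nan)
    ok = ~mask
    log2f[ok] = np.log2(s[ok] / c[ok])
    return MarkerFrequencyProfile(
        replicon=sample.replicon,
        window_bp=sample.window_bp,
        axis_kb=(sample.window_starts + sample.window_bp / 2) / 1000.0,
        log2_freq=log2f,
        mask=mask,
        genomic_start=sample.window_starts.copy(),
    )


def normalize_genome(
    samples: dict[str, CoverageTrack], controls: dict[str, CoverageTrack]
) -> dict[str, MarkerFrequencyProfile]:
    """Normalise every replicon against its control using genome-wide totals.

    With a shared total, the terminus frequencies of synchronously
    terminating replicons are directly comparable (and equal in
    expectation), so cross-replicon ratios such as a Chr2 locus over the
    Chr1 terminus are meaningful.
    """
    if set(samples) != set(controls):
        raise ValueError("samples and controls cover different replicons")
    s_total = sum(t.counts.sum() for t in samples.values())
    c_total = sum(t.counts.sum() for t in controls.values())
    return {
        name: normalize_to_control(samples[name], controls[name], s_total, c_total)
        for name in samples
    }


def to_ter_ori_ter(
    profile: MarkerFrequencyProfile, layout: GenomeLayout
) -> MarkerFrequencyProfile:
    """Reorder windows onto the ter-ori-ter axis (origin at the centre).

    A bijective re-indexing: the axis starts at the terminus, rises through
    the origin at the midpoint, and returns to the terminus.  Windows are
    rotated so the one containing ter comes first; no window is dropped or
    duplicated.
    """
    if profile.ter_ori_ter:
        return profile
    rep = layout.replicon(profile.replicon)
    # rotate so the window containing the terminus is first
    ter_idx = int(rep.ter_bp // profile.window_bp) % profile.n_windows
    order = (np.arange(profile.n_windows) + ter_idx) % profile.n_windows
    n = profile.n_windows
    return MarkerFrequencyProfile(
        replicon=profile.replicon,
        window_bp=profile.window_bp,
        axis_kb=(np.arange(n) + 0.5) * profile.window_bp / 1000.0,
        log2_freq=profile.log2_freq[order],
        mask=profile.mask[order],
        genomic_start=profile.genomic_start[order],
        ter_ori_ter=True,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_replichore_slope(
    profile: MarkerFrequencyProfile, side: str, min_windows: int = 30
) -> tuple[float, float, float]:
    """OLS slope of log2 frequency vs kb from ter to ori on one replichore.

    ``side`` is ``"left"`` (first half of the ter-ori-ter axis) or
    ``"right"`` (second half).  Both slopes are reported with the positive-
    toward-ori sign convention, so a symmetric profile gives equal slopes.
    """
    if not profile.ter_ori_ter:
        raise ValueError("profile must be on the ter-ori-ter axis; apply to_ter_ori_ter")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    n = profile.n_windows
    mid = n // 2
    idx = np.arange(0, mid) if side == "left" else np.arange(mid, n)
    keep = idx[~profile.mask[idx]]
    if len(keep) < min_windows:
        raise ValueError(f"only {len(keep)} unmasked windows on {side} replichore")
    x = profile.axis_kb[keep]
    y = profile.log2_freq[keep]
    slope, intercept, r2 = _ols(x, y)
    if side == "right":  # axis runs ori->ter on the right arm; flip sign
        slope = -slope
    return slope, intercept, r2


def _zone_mean(
    profile: MarkerFrequencyProfile, center_kb: float, n_windows: int
) -> float:
    """Mean linear-scale frequency over n contiguous windows centred on an axis point.

    On the ter-ori-ter axis the chromosome is circular, so zones wrap around
    the axis ends (the terminus zone straddles both).  Ties at zone edges
    resolve toward higher axis positions (toward ori on the left arm).
    """
    center_idx = int(np.argmin(np.abs(profile.axis_kb - center_kb)))
    lo = center_idx - (n_windows - 1) // 2
    sel = np.arange(lo, lo + n_windows)
    if profile.ter_ori_ter:
        sel = sel % profile.n_windows
    else:
        sel = sel[(sel >= 0) & (sel < profile.n_windows)]
    sel = sel[~profile.mask[sel]]
    if len(sel) == 0:
        raise ValueError(f"zone at {center_kb} kb contains only masked windows")
    return float(np.mean(2.0 ** profile.log2_freq[sel]))


def zone_ratio(
    profile: MarkerFrequencyProfile,
    zone_center_kb: float,
    n_windows: int = DEFAULT_ZONE_WINDOWS,
    reference_center_kb: float | None = None,
) -> float:
    """Mean linear-scale frequency over a window zone, relative to a reference zone.

    Averages ``n_windows`` contiguous unmasked windows centred on
    ``zone_center_kb`` along the current axis (ties at the edges resolved
    toward higher axis positions, i.e. toward ori on the left arm) and
    divides by the same statistic at the reference (the terminus, axis 0/end,
    when ``reference_center_kb`` is None).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if reference_center_kb is None:
        if not profile.ter_ori_ter:
            raise ValueError("terminus reference requires a ter-ori-ter profile")
        reference_center_kb = 0.0
    return _zone_mean(profile, zone_center_kb, n_windows) / _zone_mean(
        profile, reference_center_kb, n_windows
    )


def locus_dosage(
    profile: MarkerFrequencyProfile,
    layout: GenomeLayout,
    locus_name: str,
    reference_profile: MarkerFrequencyProfile | None = None,
) -> float:
    """Mean frequency over all windows overlapping a locus, over the ter zone.

    The locus zone spans every window overlapping the annotated interval
    (for S10, the whole VC2569-VC2599 region, not just its endpoints).  The
    terminus reference is taken from ``reference_profile`` (e.g. Chr1 when
    the locus sits on Chr2) or from the locus's own profile.
    """
    locus = layout.locus(locus_name)
    if locus.replicon != profile.replicon:
        raise ValueError(f"locus {locus_name} is not on replicon {profile.replicon}")
    w = profile.window_bp
    starts = profile.genomic_start
    overlap = (starts < locus.end_bp) & (starts + w > locus.start_bp)
    sel = overlap & ~profile.mask
    if not sel.any():
        raise ValueError(f"no unmasked windows overlap locus {locus_name}")
    locus_mean = float(np.mean(2.0 ** profile.log2_freq[sel]))

    ref = reference_profile if reference_profile is not None else profile
    if not ref.ter_ori_ter:
        raise ValueError("reference profile must be on the ter-ori-ter axis")
    ter_mean = _zone_mean(ref, 0.0, DEFAULT_ZONE_WINDOWS)
    return locus_mean / ter_mean


def estimate_C_over_tau(mean_slope: float, replichore_len_kb: float) -> float:
    """Invert the slope relation: C/tau = slope [log2/kb] x replichore length [kb]."""
    return mean_slope * replichore_len_kb


def analyze_profile(
    profile: MarkerFrequencyProfile,
    layout: GenomeLayout,
    locus_names: tuple[str, ...] = (),
    zone_windows: int = DEFAULT_ZONE_WINDOWS,
) -> MfaResult:
    """Full per-replicon MFA summary: slopes, ori/ter ratio, locus dosages.

    The profile must already be on the ter-ori-ter axis.  ``mean_slope`` is
    the mean of the two replichores' absolute slopes; fits with R^2 below
    0.95 raise a QC flag but are still reported.
    """
    sl, il, r2l = fit_replichore_slope(profile, "left")
    sr, ir, r2r = fit_replichore_slope(profile, "right")
    ori_kb = profile.axis_kb[profile.n_windows // 2]
    ori = zone_ratio(profile, ori_kb, zone_windows)
    flags = []
    if r2l < R2_QC_THRESHOLD:
        flags.append(f"left_r2_below_{R2_QC_THRESHOLD}")
    if r2r < R2_QC_THRESHOLD:
        flags.append(f"right_r2_below_{R2_QC_THRESHOLD}")
    dosages = {
        name: locus_dosage(profile, layout, name)
        for name in locus_names
        if layout.locus(name).replicon == profile.replicon
    }
    return MfaResult(
        slope_left=sl,
        slope_right=sr,
        intercept_left=il,
        intercept_right=ir,
        r2_left=r2l,
        r2_right=r2r,
        mean_slope=(abs(sl) + abs(sr)) / 2.0,
        ori_freq=ori,
        ter_freq=1.0,
        ori_ter_ratio=ori,
        locus_dosages=dosages,
        qc_flags=tuple(flags),
    )
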