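"""Replication-associated gene dosage in a fast-growing two-chromosome bacterium.

In an exponentially growing culture with overlapping replication rounds
(multifork replication), the steady-state copy number of a chromosomal marker
relative to the terminus is

    N(m) / N(ter) = 2 ** ((C / tau) * (1 - m))

where ``m`` is the relative ori->ter position of the marker along its
replichore (0 at the origin, 1 at the terminus), ``C`` is the time a fork
needs to replicate the chromosome and ``tau`` the culture doubling time.
The post-replication period ``D`` shifts absolute copy numbers by a factor
``2**(D/tau)`` that cancels from every ratio used here.

The secondary chromosome of *Vibrio cholerae* initiates late — its origin
fires once two thirds of Chr1 has been duplicated — and both replicons
terminate together, so Chr2 behaves like a chromosome with a shorter
replication period ``C2 = C1 * (1 - crts_fraction)`` and shares the terminus
copy number of Chr1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Replicon",
    "Locus",
    "GenomeLayout",
    "CellCycleParams",
    "StrainConfig",
    "relative_position",
    "marker_frequency",
    "expected_profile",
    "montecarlo_copy_number",
    "theoretical_slope",
    "default_layout",
]


@dataclass(frozen=True)
class Replicon:
    """A circular replicon with a bidirectional origin.

    The terminus is taken diametrically opposite the origin, giving two
    replichores of equal length ``length_bp / 2``.
    """

    name: str
    length_bp: int
    ori_bp: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be > 0, got {self.length_bp}")
        if not (0 <= self.ori_bp < self.length_bp):
            raise ValueError(
                f"ori_bp {self.ori_bp} outside [0, {self.length_bp}) for {self.name}"
            )

    @property
    def replichore_bp(self) -> float:
        return self.length_bp / 2

    @property
    def ter_bp(self) -> float:
        """Terminus coordinate (diametrically opposite the origin)."""
        return (self.ori_bp + self.length_bp / 2) % self.length_bp


@dataclass(frozen=True)
class Locus:
    """A named interval, 0-based half-open, on one replicon."""

    name: str
    replicon: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_bp < self.end_bp):
            raise ValueError(f"invalid interval [{self.start_bp}, {self.end_bp})")


@dataclass(frozen=True)
class GenomeLayout:
    """Replicon geometry plus locus annotations."""

    replicons: tuple[Replicon, ...]
    loci: tuple[Locus, ...] = ()

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("layout needs at least one replicon")
        names = {r.name for r in self.replicons}
        for locus in self.loci:
            if locus.replicon not in names:
                raise ValueError(f"locus {locus.name} on unknown replicon {locus.replicon}")
            if locus.end_bp > self.replicon(locus.replicon).length_bp:
                raise ValueError(f"locus {locus.name} extends past replicon end")

    def replicon(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)


@dataclass(frozen=True)
class CellCycleParams:
    """Doubling time and replication periods of the two-replicon cell cycle.

    Parameters
    ----------
    tau_min : float
        Culture doubling time, minutes.
    C1_min : float
        Chr1 replication period (ori1 firing to termination), minutes.
    D_min : float
        Post-termination period, minutes.  All dosage *ratios* are
        independent of it; kept for completeness, default 0.
    crts_fraction : float
        Fraction of Chr1 replicated when ori2 fires (default 2/3); both
        replicons terminate synchronously, so ``C2 = C1 * (1 - crts_fraction)``.
    """

    tau_min: float = 30.0
    C1_min: float = 40.0
    D_min: float = 0.0
    crts_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0 or self.C1_min <= 0:
            raise ValueError("tau_min and C1_min must be positive")
        if self.D_min < 0:
            raise ValueError("D_min must be >= 0")
        if not (0 < self.crts_fraction < 1):
            raise ValueError("crts_fraction must lie in (0, 1)")

    @property
    def C2_min(self) -> float:
        return self.C1_min * (1.0 - self.crts_fraction)

    def C_for(self, replicon_index: int) -> float:
        """Replication period for the i-th replicon (0 = Chr1, 1 = Chr2)."""
        return self.C1_min if replicon_index == 0 else self.C2_min


@dataclass(frozen=True)
class StrainConfig:
    """Placement of the ribosomal-protein (S10) locus in one strain."""

    strain_id: str
    s10_replicon: str
    s10_start_bp: int
    tau_min: float
    notes: str = ""


# Default fixture geometry: V. cholerae-like two-replicon genome with the
# S10 ribosomal-protein locus 190 kb clockwise of ori1.
S10_LENGTH_BP = 13_400
PARENTAL_S10_START_BP = 190_000


def default_layout() -> GenomeLayout:
    """Two-replicon fixture layout (Chr1 2.96 Mb, Chr2 1.07 Mb, ori at 0)."""
    chr1 = Replicon("chr1", 2_960_000, ori_bp=0)
    chr2 = Replicon("chr2", 1_070_000, ori_bp=0)
    s10 = Locus("S10", "chr1", PARENTAL_S10_START_BP, PARENTAL_S10_START_BP + S10_LENGTH_BP)
    return GenomeLayout(replicons=(chr1, chr2), loci=(s10,))


def relative_position(layout: GenomeLayout, replicon: str, pos_bp: float) -> float:
    """Relative ori->ter position ``m`` in [0, 1] of a coordinate.

    ``m`` is the circular ori distance divided by the replichore length; the
    two replichores are mirror images, so positions equidistant from the
    origin on either arm share the same ``m``.
    """
    rep = layout.replicon(replicon)
    if not (0 <= pos_bp < rep.length_bp):
        raise ValueError(
            f"position {pos_bp} outside [0, {rep.length_bp}) on {replicon}"
        )
    d = abs(pos_bp - rep.ori_bp)
    d = min(d, rep.length_bp - d)  # circular ori distance
    return d / rep.replichore_bp


def marker_frequency(m, C_min: float, tau_min: float):
    """Steady-state copy number of a marker relative to the terminus.

    Returns ``2 ** ((C/tau) * (1 - m))``; vectorised over ``m``.
    """
    if C_min <= 0 or tau_min <= 0:
        raise ValueError("C_min and tau_min must be positive")
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("m must lie in [0, 1]")
    out = 2.0 ** ((C_min / tau_min) * (1.0 - m))
    return float(out) if out.ndim == 0 else out


def theoretical_slope(params: CellCycleParams, replichore_len_kb: float) -> float:
    """Expected log2-frequency change per kb along a replichore.

    Magnitude ``(C/tau) / L``; sign convention positive from ter toward ori.
    ``C = 0`` (no replication) is allowed and gives 0.
    """
    if replichore_len_kb <= 0:
        raise ValueError("replichore_len_kb must be positive")
    return (params.C1_min / params.tau_min) / replichore_len_kb


def expected_profile(
    layout: GenomeLayout, params: CellCycleParams, window_bp: int = 1000
) -> pd.DataFrame:
    """Expected relative copy-number per window for every replicon.

    Chr1 windows use ``C1``; later replicons use ``C2``, so that with
    synchronous termination both termini share frequency 1 (the
    normalisation reference).  Windows that do not divide the replicon
    length evenly are emitted short and flagged ``partial``.

    Returns a frame with columns ``replicon, start, end, m, freq, partial``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    frames = []
    for i, rep in enumerate(layout.replicons):
        starts = np.arange(0, rep.length_bp, window_bp)
        ends = np.minimum(starts + window_bp, rep.length_bp)
        mid = (starts + ends) / 2.0
        m = np.array([relative_position(layout, rep.name, x) for x in mid])
        freq = marker_frequency(m, params.C_for(i), params.tau_min)
        frames.append(
            pd.DataFrame(
                {
                    "replicon": rep.name,
                    "start": starts.astype(int),
                    "end": ends.astype(int),
                    "m": m,
                    "freq": freq,
                    "partial": (ends - starts) != window_bp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def montecarlo_copy_number(
    m: float,
    params: CellCycleParams,
    n_cells: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of ``marker_frequency`` from single-cell sampling.

    Independent oracle for the closed form: cell ages are drawn from the
    exponential-culture age density ``p(a) = (2 ln2 / tau) 2**(-a/tau)`` on
    ``[0, tau)``.  Replication rounds initiate every ``tau`` minutes; the
    round completing at a division passes marker ``m`` at ``C*(1-m) + D``
    minutes before that division, so a cell of age ``a`` carries
    ``2**floor((C(1-m) + D + a) / tau)`` copies.  The ratio of the sampled
    mean to the (paired) sampled terminus mean is returned with a
    delta-method standard error.

    Returns
    -------
    (ratio, se) : tuple of float
    """
    if n_cells < 1000:
        raise ValueError("n_cells must be >= 1000")
    if not (0 <= m <= 1):
        raise ValueError("m must lie in [0, 1]")
    tau, C, D = params.tau_min, params.C1_min, params.D_min
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling of the age distribution: F(a) = 2(1 - 2^(-a/tau))
    u = rng.random(n_cells)
    ages = -tau * np.log2(1.0 - u / 2.0)

    def copies(pos_m: float) -> np.ndarray:
        x = C * (1.0 - pos_m) + D + ages
        return 2.0 ** np.floor(x / tau + 1e-12)

    cm = copies(m)
    ct = copies(1.0)
    ratio = cm.mean() / ct.mean()
    # delta method for the ratio of two (paired) sample means
    n = float(n_cells)
    var = (
        cm.var(ddof=1) / cm.mean() ** 2
        + ct.var(ddof=1) / ct.mean() ** 2
        - 2 * np.cov(cm, ct, ddof=1)[0, 1] / (cm.mean() * ct.mean())
    ) / n
    se = ratio * np.sqrt(max(var, 0.0))
    return float(ratio), float(se)
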