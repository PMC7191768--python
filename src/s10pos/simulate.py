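"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is deterministic given (config, seed): sequencing coverage
with the multifork ori->ter dosage gradient (Poisson window counts),
differential-expression tables with prescribed marginals, gene-to-category
maps with controllable enrichment, single-exponential fluorescence-recovery
traces, and logistic OD600 growth curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    PARENTAL_S10_START_BP,
    CellCycleParams,
    GenomeLayout,
    StrainConfig,
    expected_profile,
    relative_position,
)
from .mfa import CoverageTrack

__all__ = [
    "SimulationConfig",
    "DEEffectSpec",
    "simulate_mfa_coverage",
    "simulate_strain_set",
    "simulate_de_table",
    "simulate_frap_trace",
    "simulate_growth_curve",
    "simulate_category_map",
    "TABLE1_EFFECTS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-coverage simulation settings.

    ``coverage`` is the expected mean read count per window (100 = the
    100x-coverage scale of the real experiments, one count standing for one
    window-length equivalent of sequence); total expected depth is
    ``coverage * n_windows``.
    """

    coverage: float = 100.0
    window_bp: int = 1000
    phase: str = "exponential"  # or "stationary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.phase not in ("exponential", "stationary"):
            raise ValueError("phase must be 'exponential' or 'stationary'")


@dataclass(frozen=True)
class DEEffectSpec:
    """Marginal structure of a differential-expression table.

    Defaults reproduce the most affected strain of the study set
    (439 up, mean log2FC 0.78 +/- 0.56; 303 down, -0.52 +/- 0.29).
    """

    n_genes: int = 3700
    n_up: int = 439
    n_down: int = 303
    mean_up: float = 0.78
    sd_up: float = 0.56
    mean_down: float = -0.52
    sd_down: float = 0.29
    null_log2fc_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.sd_up < 0 or self.sd_down < 0 or self.null_log2fc_sd < 0:
            raise ValueError("sd values must be >= 0")
        if self.mean_down > 0:
            raise ValueError("mean_down must be <= 0")


# Table-1 marginal structure per movant strain:
# (n_up, mean_up, sd_up, n_down, mean_down, sd_down)
TABLE1_EFFECTS = {
    "S10Tnp-35": DEEffectSpec(n_up=2, n_down=6, mean_up=1.2, sd_up=0.4,
                              mean_down=-1.1, sd_down=0.4),
    "S10Tnp-510": DEEffectSpec(n_up=62, n_down=49, mean_up=1.5, sd_up=0.97,
                               mean_down=-0.5, sd_down=0.24),
    "S10Tnp-1120": DEEffectSpec(n_up=361, n_down=301, mean_up=0.67, sd_up=0.41,
                                mean_down=-0.49, sd_down=0.26),
    "S10TnpC2+479": DEEffectSpec(n_up=439, n_down=303, mean_up=0.78, sd_up=0.56,
                                 mean_down=-0.52, sd_down=0.29),
}


def simulate_mfa_coverage(
    layout: GenomeLayout,
    params: CellCycleParams,
    config: SimulationConfig,
) -> dict[str, CoverageTrack]:
    """Poisson window counts following the multifork dosage gradient.

    Exponential phase: window means proportional to the expected
    copy-number profile.  Stationary phase: uniform means (no ongoing
    replication).  Returns one track per replicon.
    """
    prof = expected_profile(layout, params, config.window_bp)
    if config.phase == "stationary":
        f = np.ones(len(prof))
    else:
        f = prof["freq"].to_numpy()
    depth = config.coverage * len(prof)
    mean = depth * f / f.sum()
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(mean)
    tracks: dict[str, CoverageTrack] = {}
    for rep in layout.replicons:
        sel = (prof["replicon"] == rep.name).to_numpy()
        tracks[rep.name] = CoverageTrack(
            replicon=rep.name,
            window_bp=config.window_bp,
            window_starts=prof.loc[sel, "start"].to_numpy(),
            counts=counts[sel],
        )
    return tracks


# Named strains: S10 offsets (kb from the origin of the named replicon).
STRAIN_POSITIONS = {
    "Parental": ("chr1", PARENTAL_S10_START_BP),
    "S10Tnp-35": ("chr1", 35_000),
    "S10Tnp+166": ("chr1", 166_000),
    "S10Tnp-510": ("chr1", 510_000),
    "S10Tnp-1120": ("chr1", 1_120_000),
    "S10TnpC2+37": ("chr2", 37_000),
    "S10TnpC2+479": ("chr2", 479_000),
}


def effective_position_kb(
    layout: GenomeLayout, params: CellCycleParams, replicon: str, pos_bp: int
) -> float:
    """Chr1-equivalent S10 position (kb from ori1) with the same expected dosage.

    Chr1 positions map to their ori1 distance.  A Chr2 position at relative
    coordinate ``m2`` has dosage ``2**((C2/tau)(1-m2))``; the Chr1 position
    with equal dosage satisfies ``(C1/tau)(1-m_eff) = (C2/tau)(1-m2)``.
    This is the ordering the relocation set is plotted on (Chr2 strains fall
    beyond the distal Chr1 strains).
    """
    m = relative_position(layout, replicon, pos_bp)
    chr1 = layout.replicons[0]
    if replicon == chr1.name:
        return m * chr1.replichore_bp / 1000.0
    m_eff = 1.0 - (1.0 - params.crts_fraction) * (1.0 - m)
    return m_eff * chr1.replichore_bp / 1000.0


def simulate_strain_set(
    layout: GenomeLayout,
    base_params: CellCycleParams,
    effect_slope_per_kb: float = 0.12 / 930.0,
) -> list[StrainConfig]:
    """The seven-strain relocation set with a monotone growth-rate effect.

    Growth rate relative to the parental strain declines linearly with the
    effective ori1 distance beyond the parental position and is clamped at
    the parental value (relocations closer to ori1 gain nothing).  The
    default slope makes the most distal Chr1 strain grow 12% slower, the
    reported magnitude for the most affected relocations.  This dosage->mu
    mapping is a synthetic modelling choice — the study reports the
    association, not a functional form — and exists so end-to-end tests
    have a known effect sign.
    """
    parental_eff = effective_position_kb(
        layout, base_params, *STRAIN_POSITIONS["Parental"]
    )
    strains = []
    for name, (rep, pos) in STRAIN_POSITIONS.items():
        eff = effective_position_kb(layout, base_params, rep, pos)
        rel_mu = max(0.1, 1.0 - effect_slope_per_kb * max(0.0, eff - parental_eff))
        strains.append(
            StrainConfig(
                strain_id=name,
                s10_replicon=rep,
                s10_start_bp=pos,
                tau_min=base_params.tau_min / rel_mu,
                notes=f"effective_position_kb={eff:.1f} rel_mu={rel_mu:.4f}",
            )
        )
    return strains


def simulate_de_table(spec: DEEffectSpec, seed: int = 0) -> pd.DataFrame:
    """Per-gene (gene_id, log2fc, padj) table with exact requested marginals.

    Exactly ``n_up`` genes get padj < 0.05 with positive log2FC drawn from a
    positive-truncated Normal(mean_up, sd_up); ``n_down`` analogously with
    negative values; all remaining genes get padj >= 0.05 and small
    zero-centred log2FC.  Adjusted p-values are generated directly since the
    pipeline consumes DESeq2-style adjusted tables.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_genes
    gene_ids = np.array([f"VC{i:04d}" for i in range(n)])

    def truncated(mean: float, sd: float, size: int, sign: int) -> np.ndarray:
        if size == 0:
            return np.zeros(0)
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
            draw = draw[sign * draw > 0]
            take = min(len(draw), size - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out

    log2fc = np.empty(n)
    padj = np.empty(n)
    log2fc[: spec.n_up] = truncated(spec.mean_up, spec.sd_up, spec.n_up, +1)
    log2fc[spec.n_up : spec.n_up + spec.n_down] = truncated(
        spec.mean_down, spec.sd_down, spec.n_down, -1
    )
    n_null = n - spec.n_up - spec.n_down
    log2fc[spec.n_up + spec.n_down :] = rng.normal(0.0, spec.null_log2fc_sd, n_null)
    padj[: spec.n_up + spec.n_down] = rng.uniform(0.0, 0.049, spec.n_up + spec.n_down)
    padj[spec.n_up + spec.n_down :] = rng.uniform(0.05, 1.0, n_null)
    order = rng.permutation(n)
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": log2fc[order], "padj": padj[order]}
    )


def simulate_frap_trace(
    tau_half_ms: float,
    F_pre: float = 100.0,
    F_bleach: float = 20.0,
    F_inf: float = 80.0,
    dt_ms: float = 20.0,
    duration_ms: float = 6000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pre_frames: int = 5,
    cell_length_um: float = 4.0,
    cell_id: str = "cell",
) -> pd.DataFrame:
    """Single-exponential fluorescence recovery trace (long-format frame).

    Post-bleach signal: ``F(t) = F_inf - (F_inf - F_bleach) * 2**(-t/tau_half)``
    plus Normal(0, noise_sd) noise; preceded by ``n_pre_frames`` pre-bleach
    frames at ``F_pre``.  Columns: cell_id, role, cell_length_um, time_ms,
    fluorescence, pre_bleach.
    """
    if tau_half_ms <= 0:
        raise ValueError("tau_half_ms must be positive")
    if not (F_bleach < F_inf <= F_pre):
        raise ValueError("need F_bleach < F_inf <= F_pre")
    rng = np.random.default_rng(seed)
    t_post = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    f_post = F_inf - (F_inf - F_bleach) * 2.0 ** (-t_post / tau_half_ms)
    t_pre = -dt_ms * np.arange(n_pre_frames, 0, -1)
    f_pre = np.full(n_pre_frames, F_pre)
    t = np.concatenate([t_pre, t_post])
    f = np.concatenate([f_pre, f_post])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, len(f))
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "role": "bleached",
            "cell_length_um": cell_length_um,
            "time_ms": t,
            "fluorescence": f,
            "pre_bleach": t < 0,
        }
    )


def simulate_growth_curve(
    mu_per_h: float,
    od0: float = 0.001,
    carrying_capacity: float = 1.5,
    dt_min: float = 5.0,
    duration_min: float = 600.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic OD600 curve sampled every ``dt_min`` (default 5 min).

    The exponential-phase specific growth rate is ``mu_per_h`` in natural-log
    units per hour; noise is multiplicative log-normal with sigma
    ``noise_sd``.  Columns: time_min, od600.
    """
    if mu_per_h < 0:
        raise ValueError("mu_per_h must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    r = mu_per_h / 60.0  # per minute
    if np.isinf(carrying_capacity):
        od = od0 * np.exp(r * t)
    else:
        K = carrying_capacity
        od = K * od0 * np.exp(r * t) / (K + od0 * (np.exp(r * t) - 1.0))
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, len(t)))
    return pd.DataFrame({"time_min": t, "od600": od})


def simulate_category_map(
    n_genes: int = 3700,
    n_categories: int = 25,
    enriched: list[tuple[str, float]] | None = None,
    de_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Gene->category map plus a coupled set of differentially expressed genes.

    Genes are assigned to ``n_categories`` labels multinomially (uniform);
    each gene is then flagged differentially expressed with baseline odds
    ``de_fraction / (1 - de_fraction)``, multiplied by the odds ratio of its
    category when listed in ``enriched``.

    Returns (map frame with columns gene_id, category; set of DE gene ids).
    """
    if enriched is None:
        enriched = []
    odds_ratios = dict(enriched)
    if any(v <= 0 for v in odds_ratios.values()):
        raise ValueError("odds ratios must be > 0")
    rng = np.random.default_rng(seed)
    cats = np.array([f"C{j:02d}" for j in range(n_categories)])
    gene_ids = np.array([f"VC{i:04d}" for i in range(n_genes)])
    assignment = cats[rng.integers(0, n_categories, n_genes)]
    base_odds = de_fraction / (1.0 - de_fraction)
    odds = base_odds * np.array([odds_ratios.get(c, 1.0) for c in assignment])
    p_de = odds / (1.0 + odds)
    de_flags = rng.random(n_genes) < p_de
    cat_map = pd.DataFrame({"gene_id": gene_ids, "category": assignment})
    return cat_map, set(gene_ids[de_flags])
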