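"""End-to-end orchestration: simulated strain set -> MFA -> strain table -> associations.

Chains the generators and analysis stages for the seven-strain relocation
set: per strain, simulate exponential-phase coverage and a stationary
parental control, run the marker-frequency analysis, estimate the growth
rate from a simulated OD curve, and assemble the per-strain summary table
that feeds the correlation analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import (
    S10_LENGTH_BP,
    CellCycleParams,
    GenomeLayout,
    Locus,
    StrainConfig,
    default_layout,
)
from .growth import StrainSummary, estimate_mu, strain_association
from .mfa import analyze_profile, locus_dosage, normalize_genome, to_ter_ori_ter
from .simulate import (
    SimulationConfig,
    effective_position_kb,
    simulate_growth_curve,
    simulate_mfa_coverage,
    simulate_strain_set,
)

__all__ = ["strain_layout", "run_strain_mfa", "build_strain_table", "run_all"]


def strain_layout(base: GenomeLayout, strain: StrainConfig) -> GenomeLayout:
    """The base layout with the S10 locus moved to the strain's position."""
    s10 = Locus("S10", strain.s10_replicon, strain.s10_start_bp,
                strain.s10_start_bp + S10_LENGTH_BP)
    others = tuple(l for l in base.loci if l.name != "S10")
    return GenomeLayout(replicons=base.replicons, loci=others + (s10,))


def run_strain_mfa(
    strain: StrainConfig,
    base_params: CellCycleParams,
    coverage: float = 100.0,
    window_bp: int = 1000,
    seed: int = 0,
) -> dict:
    """Simulate and analyse one strain's MFA experiment.

    Exponential-phase coverage uses the strain's own doubling time; the
    control is a stationary-phase parental culture (uniform coverage).
    Returns the Chr1 analysis plus the S10 dosage (taken on whichever
    replicon carries the locus, terminus reference on Chr1).
    """
    layout = strain_layout(default_layout(), strain)
    params = CellCycleParams(
        tau_min=strain.tau_min,
        C1_min=base_params.C1_min,
        D_min=base_params.D_min,
        crts_fraction=base_params.crts_fraction,
    )
    exp_tracks = simulate_mfa_coverage(
        layout, params, SimulationConfig(coverage, window_bp, "exponential", seed)
    )
    stat_tracks = simulate_mfa_coverage(
        layout, params, SimulationConfig(coverage, window_bp, "stationary", seed + 1)
    )
    profiles = {
        name: to_ter_ori_ter(prof, layout)
        for name, prof in normalize_genome(exp_tracks, stat_tracks).items()
    }
    chr1_result = analyze_profile(profiles["chr1"], layout)
    dosage = locus_dosage(
        profiles[strain.s10_replicon], layout, "S10",
        reference_profile=profiles["chr1"],
    )
    return {
        "strain": strain,
        "layout": layout,
        "params": params,
        "profiles": profiles,
        "chr1": chr1_result,
        "s10_dosage": dosage,
    }


def build_strain_table(
    base_params: CellCycleParams | None = None,
    coverage: float = 100.0,
    window_bp: int = 1000,
    seed: int = 0,
    growth_noise_sd: float = 0.01,
    n_replicates: int = 4,
) -> pd.DataFrame:
    """Per-strain summary over the simulated seven-strain relocation set.

    Each strain's MFA statistics are averaged over ``n_replicates``
    independent simulated experiments (the study averaged at least four per
    strain).  Columns: strain_id, s10_position_kb (effective ori1 distance),
    s10_dosage, ori_ter_ratio, mean_slope, mu_per_h.
    """
    if base_params is None:
        base_params = CellCycleParams()
    layout = default_layout()
    strains = simulate_strain_set(layout, base_params)
    rows = []
    for i, strain in enumerate(strains):
        reps = [
            run_strain_mfa(
                strain, base_params, coverage, window_bp,
                seed + 100 * i + 2 * j,
            )
            for j in range(n_replicates)
        ]
        mu_true = 60.0 * np.log(2.0) / strain.tau_min
        curve = simulate_growth_curve(
            mu_true, noise_sd=growth_noise_sd, seed=seed + 100 * i + 51
        )
        mu_hat = estimate_mu(curve)
        rows.append(
            StrainSummary(
                strain_id=strain.strain_id,
                s10_position_kb=effective_position_kb(
                    layout, base_params, strain.s10_replicon, strain.s10_start_bp
                ),
                s10_dosage=float(np.mean([r["s10_dosage"] for r in reps])),
                ori_ter_ratio=float(np.mean([r["chr1"].ori_ter_ratio for r in reps])),
                mean_slope=float(np.mean([r["chr1"].mean_slope for r in reps])),
                mu_per_h=mu_hat.mu_per_h,
            ).__dict__
        )
    return pd.DataFrame(rows)


def run_all(seed: int = 0, coverage: float = 100.0) -> dict:
    """Full simulated pipeline: strain table plus the association matrix."""
    table = build_strain_table(coverage=coverage, seed=seed)
    assoc = strain_association(table)
    return {"strain_table": table, "association": assoc}
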