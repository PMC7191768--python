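"""Genome-wide transcription summaries and differential-expression bookkeeping.

Covers read-coverage normalisation (NEV, normalized expression values),
origin-region transcriptional activity with a permutation test, Table-1-style
counts of altered genes per strain, overlap of altered gene sets across
strains, and cross-strain log2-fold-change correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTrack",
    "DESummary",
    "normalize_expression",
    "ori_region_activity",
    "summarize_de",
    "overlap_altered",
    "fc_correlation",
]


@dataclass(frozen=True)
class ExpressionTrack:
    """Per-window normalized expression values (NEV) along one replicon."""

    replicon: str
    window_bp: int
    window_starts: np.ndarray
    nev: np.ndarray
    scale: float = 1e6

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_starts", np.asarray(self.window_starts))
        object.__setattr__(self, "nev", np.asarray(self.nev, dtype=float))
        if np.any(self.nev < 0):
            raise ValueError("NEV must be non-negative")


@dataclass(frozen=True)
class DESummary:
    """Altered-gene bookkeeping for one strain vs the parental strain."""

    n_up: int
    n_down: int
    n_total: int
    n_up_gt2fold: int
    n_down_gt2fold: int
    n_total_gt2fold: int
    mean_up: float
    sd_up: float
    mean_down: float
    sd_down: float
    n_zero_fc_significant: int = 0


def normalize_expression(
    counts: np.ndarray, scale: float = 1e6, replicon: str = "chr1", window_bp: int = 1000
) -> ExpressionTrack:
    """Total-count normalisation: NEV_i = count_i / sum(counts) * scale."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero counts cannot be normalised")
    return ExpressionTrack(
        replicon=replicon,
        window_bp=window_bp,
        window_starts=np.arange(len(counts)) * window_bp,
        nev=counts / total * scale,
        scale=scale,
    )


def ori_region_activity(
    track: ExpressionTrack,
    parental: ExpressionTrack,
    ori_bp: int = 0,
    flank_bp: int = 400_000,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Transcriptional activity of the origin-flanking region vs the parental track.

    Sums NEV over the ``flank_bp`` region centred on the origin (circular
    wrap allowed), reports the fold change vs the parental strain, and a
    two-sided permutation p-value obtained by shuffling window labels of the
    per-window NEV ratio (``n_permutations`` draws, seeded).

    Returns (region_nev_sum, fold_change, p_value).
    """
    if len(track.nev) != len(parental.nev) or track.window_bp != parental.window_bp:
        raise ValueError("track and parental are on different window grids")
    n = len(track.nev)
    length_bp = n * track.window_bp
    if flank_bp > length_bp:
        raise ValueError("flank region larger than replicon")
    half = flank_bp // 2
    starts = track.window_starts
    # circular distance of window centres to ori
    centre = starts + track.window_bp / 2
    d = np.abs(centre - ori_bp)
    d = np.minimum(d, length_bp - d)
    in_region = d <= half
    region_sum = float(track.nev[in_region].sum())
    parental_sum = float(parental.nev[in_region].sum())
    if parental_sum <= 0:
        raise ValueError("parental region activity is zero")
    fold = region_sum / parental_sum
    k = int(in_region.sum())
    # permutation null: the ori-region label is exchangeable across windows
    rng = np.random.default_rng(seed)
    obs = region_sum - parental_sum
    diffs = track.nev - parental.nev
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        sel = rng.choice(n, size=k, replace=False)
        perm_stats[i] = diffs[sel].sum()
    p = (np.sum(np.abs(perm_stats) >= abs(obs)) + 1) / (n_permutations + 1)
    return region_sum, fold, float(p)


def summarize_de(
    table: pd.DataFrame, alpha: float = 0.05, fold_threshold: float = 2.0
) -> DESummary:
    """Table-1-style counts: altered genes split by direction and by >2-fold.

    Altered means ``padj < alpha`` (strict); direction is the sign of log2fc;
    the >fold_threshold tallies use ``|log2fc| > log2(fold_threshold)``
    (strict).  Significant genes with log2fc exactly 0 are counted in
    neither direction and reported separately.
    """
    if len(table) == 0:
        return DESummary(0, 0, 0, 0, 0, 0, np.nan, np.nan, np.nan, np.nan)
    sig = table["padj"].to_numpy() < alpha
    fc = table["log2fc"].to_numpy()
    log_thr = np.log2(fold_threshold)
    up = sig & (fc > 0)
    down = sig & (fc < 0)
    zero = sig & (fc == 0)
    return DESummary(
        n_up=int(up.sum()),
        n_down=int(down.sum()),
        n_total=int(up.sum() + down.sum()),
        n_up_gt2fold=int((up & (np.abs(fc) > log_thr)).sum()),
        n_down_gt2fold=int((down & (np.abs(fc) > log_thr)).sum()),
        n_total_gt2fold=int((sig & (fc != 0) & (np.abs(fc) > log_thr)).sum()),
        mean_up=float(fc[up].mean()) if up.any() else np.nan,
        sd_up=float(fc[up].std(ddof=1)) if up.sum() > 1 else np.nan,
        mean_down=float(fc[down].mean()) if down.any() else np.nan,
        sd_down=float(fc[down].std(ddof=1)) if down.sum() > 1 else np.nan,
        n_zero_fc_significant=int(zero.sum()),
    )


def altered_set(table: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Gene ids with padj < alpha."""
    if table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    return set(table.loc[table["padj"] < alpha, "gene_id"])


def overlap_altered(tables: dict[str, pd.DataFrame], alpha: float = 0.05) -> dict:
    """Pairwise and full intersections of altered gene sets across strains.

    Returns a dict with per-pair intersection sizes, the all-strain
    intersection, and per-strain counts plus the fraction of each strain's
    altered genes shared with at least one other strain.
    """
    if len(tables) < 2:
        raise ValueError("need at least two strains")
    sets = {k: altered_set(t, alpha) for k, t in tables.items()}
    names = list(sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    common = set.intersection(*sets.values())
    shared_fraction = {}
    for a in names:
        others = set().union(*(sets[b] for b in names if b != a))
        shared_fraction[a] = (
            len(sets[a] & others) / len(sets[a]) if sets[a] else np.nan
        )
    return {
        "per_strain": {k: len(v) for k, v in sets.items()},
        "pairwise": pairwise,
        "all_strains": len(common),
        "shared_fraction": shared_fraction,
    }


def fc_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    gene_set: str = "shared_altered",
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes between two strains.

    ``gene_set`` selects the genes compared: ``"shared_altered"`` (altered in
    both strains) or ``"all"`` (every gene present in both tables).  Returns
    (r, two-sided p from the t distribution with n-2 df, n genes used).
    """
    merged = table_a.merge(table_b, on="gene_id", suffixes=("_a", "_b"))
    if gene_set == "shared_altered":
        merged = merged[(merged["padj_a"] < alpha) & (merged["padj_b"] < alpha)]
    elif gene_set != "all":
        raise ValueError("gene_set must be 'shared_altered' or 'all'")
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 genes to correlate")
    x = merged["log2fc_a"].to_numpy()
    y = merged["log2fc_b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in log2fc vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
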