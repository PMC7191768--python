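"""Functional-category over/under-representation among altered genes.

Each gene carries one best functional category (25 labels by default, in the
style of eggNOG/COG assignments).  Per category, a 2x2 Pearson chi-square
(no continuity correction) tests whether differentially expressed genes are
over- or under-represented; p-values are Benjamini-Hochberg adjusted across
categories.  A subsample-robustness procedure reruns the test on random
subsets of the altered genes and reports per-category stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentRecord",
    "category_enrichment",
    "bh_adjust",
    "subsample_validation",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    category: str
    n_in_de: int
    n_in_non: int
    n_out_de: int
    n_out_non: int
    chi2: float
    p: float
    padj: float
    direction: str  # "over" | "under" | "none"
    small_expected: bool  # any expected cell count < 5
    degenerate: bool  # zero margin; p undefined


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaNs (degenerate tests) are passed through and excluded from the
    adjustment; the result is tied to values, not input order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _one_category(
    category: str, in_de: int, in_non: int, out_de: int, out_non: int
) -> EnrichmentRecord:
    table = np.array([[in_de, in_non], [out_de, out_non]], dtype=float)
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        return EnrichmentRecord(
            category, in_de, in_non, out_de, out_non,
            chi2=np.nan, p=np.nan, padj=np.nan,
            direction="none", small_expected=True, degenerate=True,
        )
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    exp_in_de = expected[0, 0]
    direction = "over" if in_de > exp_in_de else ("under" if in_de < exp_in_de else "none")
    return EnrichmentRecord(
        category, in_de, in_non, out_de, out_non,
        chi2=float(chi2), p=float(p), padj=np.nan,
        direction=direction, small_expected=bool((expected < 5).any()),
        degenerate=False,
    )


def category_enrichment(
    de_genes: set[str], universe: set[str], category_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-category 2x2 Pearson chi-square of DE status x category membership.

    ``category_map`` has columns gene_id, category (one category per gene).
    Genes in the universe without a category are dropped (their count is
    returned in the frame's ``attrs["n_unmapped"]``).  Categories with a
    zero margin are emitted flagged, not silently dropped.  Returns one row
    per category with counts, chi2, raw p, BH-adjusted p and direction.
    """
    if not de_genes:
        raise ValueError("no differentially expressed genes")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    cmap = category_map.set_index("gene_id")["category"]
    mapped = universe & set(cmap.index)
    n_unmapped = len(universe) - len(mapped)
    de = de_genes & mapped
    records = []
    by_cat: dict[str, list[str]] = {}
    for g in mapped:
        by_cat.setdefault(cmap[g], []).append(g)
    n_de = len(de)
    n_all = len(mapped)
    for cat in sorted(by_cat):
        members = by_cat[cat]
        in_de = sum(1 for g in members if g in de)
        in_non = len(members) - in_de
        out_de = n_de - in_de
        out_non = (n_all - len(members)) - out_de
        records.append(_one_category(cat, in_de, in_non, out_de, out_non))
    frame = pd.DataFrame(records)
    frame["padj"] = bh_adjust(frame["p"].to_numpy())
    frame.attrs["n_unmapped"] = n_unmapped
    return frame


def subsample_validation(
    de_genes: set[str],
    universe: set[str],
    category_map: pd.DataFrame,
    fraction: float = 0.30,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stability of each category's call under DE-gene subsampling.

    Each replicate draws ``floor(fraction * |de_genes|)`` altered genes
    without replacement, reruns :func:`category_enrichment` (BH re-applied
    within each replicate), and records which categories reach adjusted
    p < alpha.  Returns per-category stability fractions plus the full-set
    result; ``attrs["reps"]`` and ``attrs["fraction"]`` record the settings
    actually used.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    k = int(np.floor(fraction * len(de_genes)))
    if k < 1:
        raise ValueError("subsample would contain fewer than 1 gene")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(de_genes))
    hits: dict[str, int] = {}
    for _ in range(reps):
        sub = set(rng.choice(genes, size=k, replace=False))
        res = category_enrichment(sub, universe, category_map)
        for cat, padj in zip(res["category"], res["padj"]):
            if not np.isnan(padj) and padj < alpha:
                hits[cat] = hits.get(cat, 0) + 1
    full = category_enrichment(de_genes, universe, category_map)
    out = full[["category", "chi2", "p", "padj", "direction"]].copy()
    out["stability"] = [hits.get(c, 0) / reps for c in out["category"]]
    out.attrs["reps"] = reps
    out.attrs["fraction"] = fraction
    return out
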