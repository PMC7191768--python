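"""Readers and writers for the plain-text formats the pipeline consumes.

Coverage as 4-column bedGraph (0-based half-open), genome layout as a
replicon TSV plus locus GFF3, DE tables and category maps as TSV, FRAP
traces and growth curves as CSV.  All coordinates are 0-based half-open on
disk and in memory (GFF3, which is 1-based inclusive on disk, is converted
on the way in and out).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Locus, Replicon
from .mfa import CoverageTrack

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_layout",
    "write_layout",
    "read_de_table",
    "read_category_map",
]


def read_bedgraph(path, replicon: str | None = None) -> CoverageTrack:
    """Load a windowed coverage track from a 4-column bedGraph."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    if replicon is not None:
        df = df[df["chrom"] == replicon]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"expected a single replicon per track, found {list(chroms)}")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError("windows must have uniform width")
    return CoverageTrack(
        replicon=str(chroms[0]),
        window_bp=int(widths[0]),
        window_starts=df["start"].to_numpy(),
        counts=df["value"].to_numpy(dtype=float),
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    track.to_bedgraph(path)


def read_layout(replicon_tsv, loci_gff3=None) -> GenomeLayout:
    """Genome layout from a replicon table (name, length_bp, ori_bp) + locus GFF3."""
    reps = pd.read_csv(replicon_tsv, sep="\t")
    replicons = tuple(
        Replicon(str(r["name"]), int(r["length_bp"]), int(r["ori_bp"]))
        for _, r in reps.iterrows()
    )
    loci: list[Locus] = []
    if loci_gff3 is not None:
        gff = pd.read_csv(
            loci_gff3, sep="\t", header=None, comment="#",
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        for _, row in gff.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", "locus"))
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            loci.append(Locus(name, str(row["seqid"]), int(row["start"]) - 1, int(row["end"])))
    return GenomeLayout(replicons=replicons, loci=tuple(loci))


def write_layout(layout: GenomeLayout, replicon_tsv, loci_gff3=None) -> None:
    pd.DataFrame(
        [
            {"name": r.name, "length_bp": r.length_bp, "ori_bp": r.ori_bp}
            for r in layout.replicons
        ]
    ).to_csv(replicon_tsv, sep="\t", index=False)
    if loci_gff3 is not None:
        with open(loci_gff3, "w") as fh:
            fh.write("##gff-version 3\n")
            for l in layout.loci:
                fh.write(
                    f"{l.replicon}\ts10pos\tregion\t{l.start_bp + 1}\t{l.end_bp}\t.\t+\t.\t"
                    f"ID={l.name};Name={l.name}\n"
                )


def read_de_table(path) -> pd.DataFrame:
    """DE table TSV with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if np.any((df["padj"] < 0) | (df["padj"] > 1)):
        raise ValueError("padj values must lie in [0, 1]")
    return df


def read_category_map(path) -> pd.DataFrame:
    """Two-column TSV gene_id -> category (one best category per gene)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "category"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"])
    if df["gene_id"].duplicated().any():
        raise ValueError("each gene must map to exactly one category")
    return df
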