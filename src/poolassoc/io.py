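"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with a header row.  Positions are 1-based
internally and in every TSV; BED files at the boundary use the community
0-based half-open convention.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PILEUP_COLUMNS = ["chrom", "pos", "ref", "allele", "pool_id", "strand", "count"]
MANIFEST_COLUMNS = ["pool_id", "status", "n_individuals", "batch"]


def write_call_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a site call matrix as a pileup-like TSV with one row per strand."""
    rows = []
    for strand, col in (("+", "fwd"), ("-", "rev")):
        part = matrix[matrix[col] > 0][["chrom", "pos", "ref", "allele", "pool_id"]]
        part = part.assign(strand=strand, count=matrix.loc[part.index, col])
        rows.append(part)
    long = pd.concat(rows).sort_values(["chrom", "pos", "allele", "pool_id", "strand"])
    long[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    """Read a pileup-like TSV back into the wide fwd/rev count format."""
    long = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pool_id": str})
    missing = set(PILEUP_COLUMNS) - set(long.columns)
    if missing:
        raise ValueError(f"pileup TSV lacks columns: {sorted(missing)}")
    wide = (
        long.pivot_table(
            index=["chrom", "pos", "ref", "allele", "pool_id"],
            columns="strand",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .reset_index()
        .rename(columns={"+": "fwd", "-": "rev"})
    )
    for col in ("fwd", "rev"):
        if col not in wide.columns:
            wide[col] = 0
    wide.columns.name = None
    return wide[["chrom", "pos", "ref", "allele", "pool_id", "fwd", "rev"]]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path, sep="\t", dtype={"pool_id": str, "status": str, "batch": str}
    )
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest TSV lacks columns: {sorted(missing)}")
    bad = set(manifest["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"manifest status must be case/control, found {sorted(bad)}")
    return manifest


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) of target regions."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={0: str},
    )
    if (bed["end"] < bed["start"]).any():
        raise ValueError("BED intervals must satisfy end >= start")
    return bed


def restrict_to_regions(table: pd.DataFrame, bed: pd.DataFrame) -> pd.DataFrame:
    """Keep rows whose 1-based ``pos`` falls inside a BED region.

    A 1-based position ``pos`` is inside the 0-based half-open interval
    ``[start, end)`` iff ``start < pos <= end``.
    """
    keep = pd.Series(False, index=table.index)
    for chrom, g in bed.groupby("chrom"):
        on_chrom = table["chrom"] == chrom
        pos = table.loc[on_chrom, "pos"]
        inside = pd.Series(False, index=pos.index)
        for start, end in g[["start", "end"]].itertuples(index=False):
            inside |= (pos > start) & (pos <= end)
        keep.loc[on_chrom] = inside
    return table[keep]


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a site-to-gene map TSV (chrom, pos, gene[, functional])."""
    gm = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    missing = {"chrom", "pos", "gene"} - set(gm.columns)
    if missing:
        raise ValueError(f"gene map lacks columns: {sorted(missing)}")
    if "functional" in gm.columns:
        gm["functional"] = gm["functional"].astype(bool)
    return gm


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
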