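"""Per-pool allele-frequency estimation from filtered base-call counts.

After filtering, base-call counts are normalised to allele frequencies per
pool using the total number of calls for the alleles designated at the site
(reference plus retained alternates), and converted to expected chromosome
counts (ECC = frequency x 2N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def estimate_pool_af(
    matrix: pd.DataFrame,
    retained: pd.DataFrame,
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pool frequency and ECC for every retained alternate allele.

    The denominator in a pool is the summed count of the designated alleles
    at the site (reference plus all retained alternates).  Pools with zero
    passing coverage at a site are flagged missing (``af`` is NaN) and carry
    zero depth; downstream regression skips them.

    Returns a long table: ``chrom, pos, ref, alt, pool_id, status,
    n_individuals, batch, count, depth, af, ecc, missing``.
    """
    if retained.empty:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "ref",
                "alt",
                "pool_id",
                "status",
                "n_individuals",
                "batch",
                "count",
                "depth",
                "af",
                "ecc",
                "missing",
            ]
        )
    df = matrix.copy()
    df["count"] = df["fwd"] + df["rev"]

    sites = retained[["chrom", "pos", "ref"]].drop_duplicates()
    designated = pd.concat(
        [
            sites.assign(allele=sites["ref"]),
            retained.rename(columns={"alt": "allele"})[
                ["chrom", "pos", "ref", "allele"]
            ],
        ]
    ).drop_duplicates()
    calls = designated.merge(df, on=["chrom", "pos", "ref", "allele"], how="left")

    # full site x pool grid so zero-coverage pools appear as missing entries
    grid = sites.merge(manifest, how="cross")
    totals = (
        calls.groupby(["chrom", "pos", "pool_id"], sort=False)["count"]
        .sum()
        .rename("depth")
    )
    alt_calls = retained.rename(columns={"alt": "allele"})[
        ["chrom", "pos", "ref", "allele"]
    ].merge(df, on=["chrom", "pos", "ref", "allele"], how="left")
    out = retained[["chrom", "pos", "ref", "alt"]].merge(
        grid, on=["chrom", "pos", "ref"], how="left"
    )
    out = out.merge(
        alt_calls.rename(columns={"allele": "alt"})[
            ["chrom", "pos", "ref", "alt", "pool_id", "count"]
        ],
        on=["chrom", "pos", "ref", "alt", "pool_id"],
        how="left",
    )
    out["count"] = out["count"].fillna(0).astype(int)
    out = out.join(totals, on=["chrom", "pos", "pool_id"])
    out["depth"] = out["depth"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["af"] = np.where(out["depth"] > 0, out["count"] / out["depth"], np.nan)
    out["ecc"] = out["af"] * 2 * out["n_individuals"]
    out["missing"] = out["depth"] == 0
    return out.sort_values(["chrom", "pos", "alt", "pool_id"]).reset_index(drop=True)


def combined_maf(
    af_table: pd.DataFrame,
    manifest: pd.DataFrame,
    group: str = "all",
) -> pd.Series:
    """Depth-weighted mean pool frequency per variant for a pool group.

    ``group`` is ``"all"``, ``"case"`` or ``"control"``.  Pools with missing
    entries contribute nothing; a variant missing in every pool of the group
    gets NaN.  Depth weighting is used because pools differ in size and
    coverage.
    """
    if group not in {"all", "case", "control"}:
        raise ValueError(f"group must be all|case|control, got {group!r}")
    sub = af_table
    if group != "all":
        keep = set(manifest.loc[manifest["status"] == group, "pool_id"])
        if not keep:
            raise ValueError(f"no pools with status {group!r} in manifest")
        sub = af_table[af_table["pool_id"].isin(keep)]
    sub = sub[~sub["missing"]]
    grouped = sub.groupby(["chrom", "pos", "ref", "alt"], sort=True)
    num = grouped.apply(
        lambda g: float(np.sum(g["af"] * g["depth"])), include_groups=False
    )
    den = grouped["depth"].sum()
    maf = num / den
    maf.name = "maf"
    return maf


def pivot_af_matrix(af_table: pd.DataFrame) -> pd.DataFrame:
    """Wide variants x pools frequency matrix (NaN where missing) for PCA."""
    tab = af_table.copy()
    tab.loc[tab["missing"], "af"] = np.nan
    return (
        tab.set_index(["chrom", "pos", "ref", "alt", "pool_id"])["af"]
        .unstack("pool_id")
    )
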