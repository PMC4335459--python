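"""Strand-aware base-call filtering for pooled sequencing.

A candidate allele in a pool is trusted only if it is seen on both strands
(at least two calls each), amounts to at least one expected chromosome count
(ECC), and each strand alone contributes at least 0.3 ECC.  An allele is
retained experiment-wide only if those per-pool criteria hold in at least
three pools spanning at least two sequencing batches.  Counts entering the
matrix are assumed to be restricted upstream to base quality Phred >= 20.

The ECC is the estimated number of chromosomes in a pool carrying an allele:
``allele calls / total calls * 2N`` for a pool of ``N`` individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced DNA pool."""

    pool_id: str
    status: str  # "case" | "control"
    n_individuals: int
    batch: str

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if self.status not in {"case", "control"}:
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")


@dataclass(frozen=True)
class FilterThresholds:
    """Per-pool and experiment-wide allele acceptance thresholds."""

    min_strand_calls: int = 2
    min_ecc: float = 1.0
    min_strand_ecc: float = 0.3
    min_pools: int = 3
    min_batches: int = 2


def expected_chromosome_count(
    allele_calls: float, total_calls: float, n_individuals: int
) -> float:
    """Expected chromosome count: ``allele_calls / total_calls * 2N``."""
    if total_calls <= 0:
        raise ValueError("total_calls must be > 0 (no usable coverage in pool)")
    if not 0 <= allele_calls <= total_calls:
        raise ValueError(
            f"allele_calls must lie in [0, total_calls], got {allele_calls}/{total_calls}"
        )
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    return allele_calls / total_calls * 2 * n_individuals


def allele_passes_in_pool(
    fwd: int,
    rev: int,
    total_calls: int,
    n_individuals: int,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[bool, dict[str, bool]]:
    """Per-pool acceptance of one allele, with per-criterion detail.

    Criteria: >= 2 calls on each strand; total ECC >= 1; and >= 0.3 ECC
    attributable to each strand.  Zero-coverage pools fail all criteria.
    """
    if fwd < 0 or rev < 0 or total_calls < fwd + rev:
        raise ValueError("counts must be non-negative with total_calls >= fwd + rev")
    if total_calls == 0:
        detail = {"strand_counts": False, "ecc": False, "strand_ecc": False}
        return False, detail
    ecc = expected_chromosome_count(fwd + rev, total_calls, n_individuals)
    ecc_fwd = expected_chromosome_count(fwd, total_calls, n_individuals)
    ecc_rev = expected_chromosome_count(rev, total_calls, n_individuals)
    detail = {
        "strand_counts": fwd >= thresholds.min_strand_calls
        and rev >= thresholds.min_strand_calls,
        "ecc": ecc >= thresholds.min_ecc,
        "strand_ecc": ecc_fwd >= thresholds.min_strand_ecc
        and ecc_rev >= thresholds.min_strand_ecc,
    }
    return all(detail.values()), detail


def retain_variant(
    passing_pools: list[str],
    manifest: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Experiment-wide retention: enough passing pools across enough batches."""
    if manifest.empty:
        raise ValueError("manifest is empty")
    batches = manifest.set_index("pool_id").loc[:, "batch"]
    pools = set(passing_pools)
    unknown = pools - set(batches.index)
    if unknown:
        raise ValueError(f"pools absent from manifest: {sorted(unknown)}")
    n_batches = batches.loc[sorted(pools)].nunique() if pools else 0
    return len(pools) >= thresholds.min_pools and n_batches >= thresholds.min_batches


def _validate_matrix(matrix: pd.DataFrame, manifest: pd.DataFrame) -> None:
    required = {"chrom", "pos", "ref", "allele", "pool_id", "fwd", "rev"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"site call matrix lacks columns: {sorted(missing)}")
    unknown = set(matrix["pool_id"]) - set(manifest["pool_id"])
    if unknown:
        raise ValueError(f"pools in matrix absent from manifest: {sorted(unknown)}")


def filter_experiment(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all filtering criteria to a site call matrix.

    Returns ``(retained, verdicts)``.  ``retained`` lists non-reference
    alleles that pass in >= ``min_pools`` pools spanning >= ``min_batches``
    batches (columns ``chrom, pos, ref, alt, n_supporting_pools, n_batches``,
    plus the supporting pool ids).  ``verdicts`` carries the per
    site x pool x allele criterion flags for every non-reference allele with
    at least one call.
    """
    if matrix.empty:
        raise ValueError("site call matrix is empty")
    _validate_matrix(matrix, manifest)
    pool_info = manifest.set_index("pool_id")

    df = matrix.copy()
    df["count"] = df["fwd"] + df["rev"]
    totals = (
        df.groupby(["chrom", "pos", "pool_id"], sort=False)["count"]
        .sum()
        .rename("total_calls")
    )
    df = df.join(totals, on=["chrom", "pos", "pool_id"])
    df["n_individuals"] = pool_info["n_individuals"].reindex(df["pool_id"]).to_numpy()
    df["batch"] = pool_info["batch"].reindex(df["pool_id"]).to_numpy()

    alt = df[df["allele"] != df["ref"]].copy()
    two_n = 2 * alt["n_individuals"].to_numpy(dtype=float)
    total = alt["total_calls"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.where(total > 0, alt["count"] / total * two_n, 0.0)
        ecc_fwd = np.where(total > 0, alt["fwd"] / total * two_n, 0.0)
        ecc_rev = np.where(total > 0, alt["rev"] / total * two_n, 0.0)
    alt["ecc"] = ecc
    alt["pass_strand_counts"] = (alt["fwd"] >= thresholds.min_strand_calls) & (
        alt["rev"] >= thresholds.min_strand_calls
    )
    alt["pass_ecc"] = ecc >= thresholds.min_ecc
    alt["pass_strand_ecc"] = (ecc_fwd >= thresholds.min_strand_ecc) & (
        ecc_rev >= thresholds.min_strand_ecc
    )
    alt["pass_pool"] = (
        alt["pass_strand_counts"] & alt["pass_ecc"] & alt["pass_strand_ecc"]
    )

    passing = alt[alt["pass_pool"]]
    if passing.empty:
        retained = pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "ref",
                "alt",
                "n_supporting_pools",
                "n_batches",
                "supporting_pools",
            ]
        )
        return retained, alt

    grouped = passing.groupby(["chrom", "pos", "ref", "allele"], sort=True)
    summary = grouped.agg(
        n_supporting_pools=("pool_id", "nunique"),
        n_batches=("batch", "nunique"),
        supporting_pools=("pool_id", lambda s: ",".join(sorted(set(s)))),
    ).reset_index()
    summary = summary.rename(columns={"allele": "alt"})
    retained = summary[
        (summary["n_supporting_pools"] >= thresholds.min_pools)
        & (summary["n_batches"] >= thresholds.min_batches)
    ].reset_index(drop=True)
    return retained, alt
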