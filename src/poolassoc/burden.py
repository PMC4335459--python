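"""Gene-level burden testing with pool-label permutation.

For a gene carrying ``n`` SNVs, the genomic-control-corrected per-SNV
chi-square (z^2) statistics are summed and referred to the chi-square
distribution with ``n`` degrees of freedom.  Because linkage disequilibrium
distributes one signal across several SNVs and inflates that sum, significant
genes are re-tested by permuting case/control status among pools, re-running
the regression and genomic control (lambda re-estimated within each
permutation) and comparing permuted to observed sums.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationData, chi2_for_permutation
from .pca import genomic_inflation

logger = logging.getLogger(__name__)


def burden_statistic(gene_chi2: np.ndarray | list[float]) -> tuple[float, float]:
    """Sum of corrected z^2 over a gene's SNVs and its chi-square(n) p-value."""
    values = np.asarray(gene_chi2, dtype=float)
    if values.size == 0:
        raise ValueError("burden_statistic needs at least one SNV")
    if (values < 0).any():
        raise ValueError("chi-square values must be non-negative")
    total = float(values.sum())
    p = float(stats.chi2.sf(total, df=values.size))
    return total, p


def _gene_rows(data: AssociationData, gene_sites: pd.DataFrame) -> np.ndarray:
    key = pd.MultiIndex.from_frame(data.variants[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(gene_sites[["chrom", "pos"]].drop_duplicates())
    rows = key.get_indexer(want)
    return rows[rows >= 0]


def permutation_pvalue(
    data: AssociationData,
    gene_rows: np.ndarray,
    analysis_rows: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    reestimate_lambda: bool = True,
) -> tuple[float, float]:
    """Permutation p-value for one gene's burden sum.

    ``gene_rows`` indexes the gene's SNVs and ``analysis_rows`` the full
    post-exclusion SNV set inside ``data`` (lambda is re-estimated from the
    latter within every permutation when ``reestimate_lambda``).  Returns
    ``(perm_p, observed_sum)`` with the add-one estimate
    ``(1 + #{permuted >= observed}) / (B + 1)``, never zero, deterministic
    given ``seed``.
    """
    if n_permutations < 999:
        raise ValueError("use at least 999 permutations")
    n_case = int(data.is_case.sum())
    n_pools = data.is_case.size
    distinct = comb(n_pools, n_case)
    B = n_permutations
    if distinct < B:
        logger.warning(
            "only %d distinct labelings available; truncating B from %d", distinct, B
        )
        B = distinct

    def corrected_gene_sum(is_case: np.ndarray) -> float:
        chi2 = chi2_for_permutation(data, is_case)
        lam = 1.0
        if reestimate_lambda:
            lam = max(genomic_inflation(chi2[analysis_rows]), 1.0)
        return float(chi2[gene_rows].sum() / lam)

    observed = corrected_gene_sum(data.is_case)
    rng = np.random.default_rng(seed)
    exceed = 0
    labels = data.is_case.copy()
    for _ in range(B):
        rng.shuffle(labels)
        if corrected_gene_sum(labels) >= observed:
            exceed += 1
    perm_p = (1 + exceed) / (B + 1)
    return perm_p, observed


def gene_burden_scan(
    associations: pd.DataFrame,
    gene_map: pd.DataFrame,
    data: AssociationData | None = None,
    functional_only: bool = False,
    n_permutations: int = 0,
    seed: int = 0,
    permute_if_p_below: float = 1.0,
) -> pd.DataFrame:
    """Burden test for every gene in the gene map.

    ``associations`` must carry post-GC, post-QC rows (``chi2_gc`` present,
    excluded and overdispersed SNVs already removed).  ``gene_map`` maps
    sites to genes (columns ``chrom, pos, gene`` and optional boolean
    ``functional``).  When ``n_permutations`` > 0 and ``data`` is given,
    genes with analytic p below ``permute_if_p_below`` also get a
    permutation p-value.
    """
    if functional_only:
        if "functional" not in gene_map.columns:
            raise ValueError("gene_map lacks a 'functional' column")
        gene_map = gene_map[gene_map["functional"].astype(bool)]
    merged = associations.merge(gene_map, on=["chrom", "pos"], how="inner")

    analysis_rows = None
    if data is not None:
        key = pd.MultiIndex.from_frame(data.variants[["chrom", "pos"]])
        analysis_rows = key.get_indexer(
            pd.MultiIndex.from_frame(associations[["chrom", "pos"]])
        )
        analysis_rows = analysis_rows[analysis_rows >= 0]

    results = []
    for gene, g in merged.groupby("gene", sort=True):
        total, p = burden_statistic(g["chi2_gc"].to_numpy())
        row = {
            "gene": gene,
            "n_snvs": len(g),
            "sum_z2": total,
            "analytic_p": p,
            "perm_p": np.nan,
            "n_permutations": 0,
            "variant_class": "functional" if functional_only else "all",
        }
        if (
            n_permutations > 0
            and data is not None
            and analysis_rows is not None
            and p < permute_if_p_below
        ):
            rows = _gene_rows(data, g)
            perm_p, _ = permutation_pvalue(
                data, rows, analysis_rows, n_permutations, seed=seed
            )
            row["perm_p"] = perm_p
            row["n_permutations"] = n_permutations
        results.append(row)
    return pd.DataFrame(results)
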