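"""Per-SNV case/control association from pool-level chromosome counts.

Each SNV is tested with a "reversed" binomial logistic regression across
pools: the response is the pool's expected chromosome count for the minor
allele out of the minor+major total (rounded to integer trials), and the
single predictor is the pool's case/control status.  This orientation
accommodates unequal pool sizes and reflects the design (status is fixed by
the experimenter, allele frequencies are not).

With a single binary covariate the binomial GLM has a closed form: the
fitted group probabilities are the group-pooled frequencies, so the 1-df
likelihood-ratio chi-square for status equals the aggregated 2x2
allele-count LR statistic and the residual deviance (n_pools - 2 df)
measures extra-binomial scatter of pools around their group frequency.
Genomic control divides every chi-square by the inflation factor lambda;
SNVs with extreme residual deviance (overdispersion) are removed as QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .pca import genomic_inflation

logger = logging.getLogger(__name__)

OVERDISPERSION_P = 1.5e-5


def _binom_ll(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of group-pooled binomial counts."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(t > 0, s / np.maximum(t, 1), 0.0)
    return xlogy(s, p) + xlogy(t - s, 1.0 - p)


def _lr_chi2(
    s_case: np.ndarray,
    t_case: np.ndarray,
    s_ctrl: np.ndarray,
    t_ctrl: np.ndarray,
) -> np.ndarray:
    """1-df LR chi-square for the status term, vectorized over SNVs."""
    ll_alt = _binom_ll(s_case, t_case) + _binom_ll(s_ctrl, t_ctrl)
    ll_null = _binom_ll(s_case + s_ctrl, t_case + t_ctrl)
    return np.maximum(2.0 * (ll_alt - ll_null), 0.0)


def snv_pool_regression(
    ecc_minor: np.ndarray,
    ecc_total: np.ndarray,
    status: np.ndarray,
) -> tuple[float, int, float, int]:
    """Pool logistic regression for one SNV.

    Parameters
    ----------
    ecc_minor, ecc_total : arrays, one entry per pool
        Expected chromosome counts for the minor allele and for minor+major
        combined.  Rounded to nearest integer (trials floored at 1 where a
        pool has any coverage); pools with zero total are dropped.
    status : array of "case"/"control" per pool.

    Returns
    -------
    (chi2, direction, residual_deviance, dof)
        ``chi2`` is the 1-df likelihood-ratio statistic for status;
        ``direction`` is +1 if the minor-allele frequency is higher in cases,
        -1 if lower, 0 if equal; ``residual_deviance`` has ``n_pools - 2``
        degrees of freedom.
    """
    ecc_minor = np.asarray(ecc_minor, dtype=float)
    ecc_total = np.asarray(ecc_total, dtype=float)
    status = np.asarray(status)
    keep = ecc_total > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 pools with nonzero total")
    s = np.rint(ecc_minor[keep]).astype(np.int64)
    t = np.maximum(np.rint(ecc_total[keep]).astype(np.int64), 1)
    s = np.minimum(s, t)
    is_case = status[keep] == "case"
    if not is_case.any() or is_case.all():
        raise ValueError("need at least one case and one control pool")
    s1, t1 = int(s[is_case].sum()), int(t[is_case].sum())
    s0, t0 = int(s[~is_case].sum()), int(t[~is_case].sum())
    chi2 = float(_lr_chi2(*(np.asarray(v, dtype=float) for v in (s1, t1, s0, t0))))
    f1, f0 = s1 / t1, s0 / t0
    direction = int(np.sign(f1 - f0))
    # residual deviance: pools around their fitted (group) frequency
    p_fit = np.where(is_case, f1, f0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = xlogy(s, np.where(p_fit > 0, s / (t * np.where(p_fit > 0, p_fit, 1)), 1.0)) + xlogy(
            t - s,
            np.where(p_fit < 1, (t - s) / (t * np.where(p_fit < 1, 1 - p_fit, 1)), 1.0),
        )
    residual_deviance = float(max(2.0 * dev_terms.sum(), 0.0))
    dof = int(keep.sum()) - 2
    return chi2, direction, residual_deviance, dof


@dataclass
class AssociationData:
    """Rounded per-pool chromosome-count matrices for a set of SNVs.

    ``successes`` and ``trials`` are SNV x pool integer arrays (minor-allele
    ECC and minor+major ECC); ``is_case`` flags case pools.  This is the
    sufficient input for the vectorized regression and for permutation
    re-analysis.
    """

    variants: pd.DataFrame  # chrom, pos, ref, alt (analysis order)
    successes: np.ndarray
    trials: np.ndarray
    is_case: np.ndarray
    pool_ids: list[str] = field(default_factory=list)

    @property
    def n_snvs(self) -> int:
        return self.successes.shape[0]


def build_association_data(
    af_table: pd.DataFrame,
    manifest: pd.DataFrame,
    excluded_pools: tuple[str, ...] = (),
) -> AssociationData:
    """Assemble per-site success/trial matrices from the pool AF table.

    At each site the two most common alleles (reference plus retained
    alternates, ranked by summed base calls over non-excluded pools, ties
    broken lexicographically by base) are designated for association.  The
    minor allele of the pair forms the successes; trials are the rounded
    minor+major expected chromosome counts.  Pools with missing coverage get
    zero trials and drop out of the fit.
    """
    excluded = set(excluded_pools)
    tab = af_table[~af_table["pool_id"].isin(excluded) & ~af_table["missing"]]
    pools = [p for p in manifest["pool_id"] if p not in excluded]
    pool_index = {p: i for i, p in enumerate(pools)}
    info = manifest.set_index("pool_id")
    is_case = np.array([info.loc[p, "status"] == "case" for p in pools])
    two_n = np.array([2.0 * info.loc[p, "n_individuals"] for p in pools])
    n_p = len(pools)

    records: list[dict] = []
    suc_rows: list[np.ndarray] = []
    tri_rows: list[np.ndarray] = []
    for (chrom, pos, ref), g in tab.groupby(["chrom", "pos", "ref"], sort=True):
        depth = np.zeros(n_p)
        alt_counts: dict[str, np.ndarray] = {}
        for alt_allele, ga in g.groupby("alt", sort=True):
            vec = np.zeros(n_p)
            cols = ga["pool_id"].map(pool_index).to_numpy()
            vec[cols] = ga["count"].to_numpy(dtype=float)
            depth[cols] = ga["depth"].to_numpy(dtype=float)
            alt_counts[alt_allele] = vec
        ref_vec = depth - sum(alt_counts.values())
        alleles = {ref: ref_vec, **alt_counts}
        ranked = sorted(alleles, key=lambda a: (-alleles[a].sum(), a))
        major, minor = ranked[0], ranked[1]
        covered = depth > 0
        ecc_minor = np.where(covered, alleles[minor] / np.maximum(depth, 1), 0) * two_n
        pair = alleles[minor] + alleles[major]
        ecc_pair = np.where(covered, pair / np.maximum(depth, 1), 0) * two_n
        s = np.rint(ecc_minor).astype(np.int64)
        t = np.rint(ecc_pair).astype(np.int64)
        t = np.where(covered & (t < 1), 1, t)
        s = np.minimum(s, t)
        records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": minor if minor != ref else major,
                "major_allele": major,
                "minor_allele": minor,
            }
        )
        suc_rows.append(s)
        tri_rows.append(t)

    variants = pd.DataFrame(
        records, columns=["chrom", "pos", "ref", "alt", "major_allele", "minor_allele"]
    )
    successes = np.vstack(suc_rows) if suc_rows else np.empty((0, n_p), dtype=np.int64)
    trials = np.vstack(tri_rows) if tri_rows else np.empty((0, n_p), dtype=np.int64)
    return AssociationData(
        variants=variants,
        successes=successes,
        trials=trials,
        is_case=is_case,
        pool_ids=pools,
    )


def _group_stats(
    data: AssociationData, is_case: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s1 = data.successes[:, is_case].sum(axis=1).astype(float)
    t1 = data.trials[:, is_case].sum(axis=1).astype(float)
    s0 = data.successes[:, ~is_case].sum(axis=1).astype(float)
    t0 = data.trials[:, ~is_case].sum(axis=1).astype(float)
    return s1, t1, s0, t0


def chi2_for_permutation(data: AssociationData, is_case: np.ndarray) -> np.ndarray:
    """Vectorized LR chi-square for all SNVs under a given status labelling."""
    s1, t1, s0, t0 = _group_stats(data, is_case)
    return _lr_chi2(s1, t1, s0, t0)


def associate_snvs(data: AssociationData) -> pd.DataFrame:
    """Fit the pool regression for every SNV; no exclusions or GC yet.

    Returns the variants table augmented with ``chi2``, ``direction``,
    ``residual_deviance``, ``resid_dof`` and the per-group minor-allele
    chromosome counts.
    """
    s1, t1, s0, t0 = _group_stats(data, data.is_case)
    chi2 = _lr_chi2(s1, t1, s0, t0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(t1 > 0, s1 / np.maximum(t1, 1), 0.0)
        f0 = np.where(t0 > 0, s0 / np.maximum(t0, 1), 0.0)
    direction = np.sign(f1 - f0).astype(int)

    informative = data.trials > 0
    p_fit = np.where(data.is_case[None, :], f1[:, None], f0[:, None])
    s = data.successes.astype(float)
    t = data.trials.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = t * p_fit
        term1 = xlogy(s, np.where((s > 0) & (mu > 0), s / np.where(mu > 0, mu, 1), 1.0))
        nu = t * (1 - p_fit)
        fail = t - s
        term2 = xlogy(
            fail, np.where((fail > 0) & (nu > 0), fail / np.where(nu > 0, nu, 1), 1.0)
        )
    dev = 2.0 * np.where(informative, term1 + term2, 0.0).sum(axis=1)
    resid_dof = informative.sum(axis=1) - 2

    out = data.variants.copy()
    out["chi2"] = np.maximum(chi2, 0.0)
    out["direction"] = direction
    out["residual_deviance"] = np.maximum(dev, 0.0)
    out["resid_dof"] = resid_dof
    out["minor_case"] = s1.astype(int)
    out["minor_control"] = s0.astype(int)
    out["total_case"] = t1.astype(int)
    out["total_control"] = t0.astype(int)
    return out


def exclude_snvs(
    associations: pd.DataFrame,
    af_table: pd.DataFrame | None = None,
    excluded_pools: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mark SNVs to drop before lambda estimation.

    Excluded: SNVs with zero minor-allele chromosome count in cases or in
    controls, and SNVs whose minor-allele support lies entirely in excluded
    (outlier) pools.
    """
    out = associations.copy()
    out["excluded"] = False
    out["exclusion_reason"] = ""
    if af_table is not None and excluded_pools:
        support = af_table[(af_table["count"] > 0) & ~af_table["missing"]]
        only_excluded = (
            support.groupby(["chrom", "pos", "ref", "alt"])["pool_id"]
            .agg(lambda s: set(s) <= set(excluded_pools))
            .rename("only_in_excluded")
        )
        key = out.set_index(["chrom", "pos", "ref", "alt"]).index
        flag = only_excluded.reindex(key).fillna(False).to_numpy(dtype=bool)
        out.loc[flag, "excluded"] = True
        out.loc[flag, "exclusion_reason"] = "only in excluded pools"
    zero = ((out["minor_case"] == 0) | (out["minor_control"] == 0)) & ~out["excluded"]
    out.loc[zero, "excluded"] = True
    out.loc[zero, "exclusion_reason"] = "zero count in case or controls"
    return out


def apply_genomic_control(
    associations: pd.DataFrame, lambda_gc: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Divide chi-squares by lambda and recompute p-values.

    Lambda is estimated from the non-excluded SNVs (median chi-square over
    0.4549) unless supplied.  Lambda below 1 is clamped to 1 (genomic control
    never deflates) and the clamp is logged.
    """
    out = associations.copy()
    mask = ~out.get("excluded", pd.Series(False, index=out.index))
    if lambda_gc is None:
        lambda_gc = genomic_inflation(out.loc[mask, "chi2"])
    if lambda_gc < 1.0:
        logger.info("lambda %.4f < 1; clamped to 1 (no deflation)", lambda_gc)
        lambda_gc = 1.0
    out["chi2_gc"] = out["chi2"] / lambda_gc
    out["p_gc"] = stats.chi2.sf(out["chi2_gc"], df=1)
    return out, float(lambda_gc)


def overdispersion_qc(
    associations: pd.DataFrame, p_threshold: float = OVERDISPERSION_P
) -> pd.DataFrame:
    """Flag SNVs with extreme residual deviance (SNV-specific overdispersion).

    A SNV is flagged when its residual deviance exceeds the chi-square
    critical value with ``resid_dof`` degrees of freedom at the threshold.
    SNVs with non-positive degrees of freedom are skipped (logged).
    """
    out = associations.copy()
    dof = out["resid_dof"].to_numpy()
    testable = dof > 0
    if not testable.all():
        logger.info(
            "overdispersion QC skipped for %d SNVs with dof <= 0", int((~testable).sum())
        )
    crit = np.full(len(out), np.inf)
    crit[testable] = stats.chi2.isf(p_threshold, df=dof[testable])
    out["overdispersion_p"] = np.where(
        testable, stats.chi2.sf(out["residual_deviance"], df=np.maximum(dof, 1)), np.nan
    )
    out["overdispersed"] = out["residual_deviance"].to_numpy() > crit
    return out
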