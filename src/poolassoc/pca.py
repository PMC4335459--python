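"""Bias diagnostics: PCA of standardized pool allele frequencies and
genomic-inflation estimation.

Case-only/control-only pool designs can confound sequencing batch effects
with phenotype.  PCA of the standardized variants x pools frequency matrix
exposes outlier pools and case/control separation; the genomic inflation
factor lambda (median association chi-square over the chi-square(1) median,
0.4549) quantifies how much residual bias inflates the association statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN: float = float(stats.chi2.median(1))


def standardize_af_matrix(af_matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each variant row to mean 0, variance 1 across pools.

    Uses the population-SD convention.  Rows with zero variance across
    non-missing pools are dropped; missing entries are mean-imputed, i.e.
    zero after standardization.
    """
    if af_matrix.shape[1] < 2:
        raise ValueError("standardization needs at least 2 pools")
    values = af_matrix.to_numpy(dtype=float)
    informative = (~np.isnan(values)).sum(axis=1) >= 2
    af_matrix = af_matrix[informative]
    values = values[informative]
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)  # population SD
    keep = sd[:, 0] > 1e-12  # tolerate float noise in constant rows
    z = (values[keep] - mean[keep]) / sd[keep]
    z = np.nan_to_num(z, nan=0.0)
    return pd.DataFrame(z, index=af_matrix.index[keep], columns=af_matrix.columns)


@dataclass(frozen=True)
class PCAResult:
    """Pool scores and variance decomposition of the standardized AF matrix."""

    scores: pd.DataFrame  # pools x axes, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    outlier_pools: tuple[str, ...] = ()


def compute_pca(standardized: pd.DataFrame, k: int = 2) -> PCAResult:
    """SVD-based PCA of the pools x variants standardized matrix.

    ``standardized`` is variants x pools as produced by
    :func:`standardize_af_matrix`; pools are the observations.
    """
    n_pools = standardized.shape[1]
    if not 1 <= k <= n_pools - 1:
        raise ValueError(f"k must lie in [1, n_pools-1]=[1, {n_pools - 1}], got {k}")
    X = standardized.to_numpy(dtype=float).T  # pools x variants
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=standardized.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        scores=frame, explained_variance_ratio=pca.explained_variance_ratio_
    )


def flag_outlier_pools(
    scores: pd.DataFrame, threshold_mads: float = 4.0
) -> list[str]:
    """Pools whose robust z-score on PC1 or PC2 exceeds the threshold.

    Robust z = |score - median| / (1.4826 * MAD) per axis.  If an axis has
    MAD 0 (scores essentially tied), that axis falls back to flagging pools
    whose score differs from the shared value, and the fallback is logged.
    """
    axes = [c for c in ("PC1", "PC2") if c in scores.columns]
    flagged: set[str] = set()
    for axis in axes:
        vals = scores[axis].to_numpy(dtype=float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            logger.warning(
                "MAD is zero on %s; falling back to rank-based flagging", axis
            )
            off = np.abs(vals - med) > 0
        else:
            robust_z = np.abs(vals - med) / (1.4826 * mad)
            off = robust_z > threshold_mads
        flagged.update(scores.index[off])
    return sorted(flagged)


def genomic_inflation(chi2_values: np.ndarray | pd.Series | list[float]) -> float:
    """Genomic inflation factor lambda = median(chi2) / chi2_1 median.

    Lambda near 1 indicates calibrated statistics; systematic case/control
    bias or overdispersion inflates it.  Median-based, hence robust to a
    handful of genuinely associated SNVs.
    """
    values = np.asarray(chi2_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("genomic_inflation needs at least one finite chi2 value")
    return float(np.median(values) / CHI2_1_MEDIAN)
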