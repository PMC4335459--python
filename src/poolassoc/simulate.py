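"""Synthetic pooled-sequencing data with matched ground truth.

The generator emulates a case-only / control-only DNA pool design: each pool
combines ``N`` individuals (``2N`` chromosomes), and sequencing reads sample
those chromosomes with depth drawn from a negative binomial.  Base-call error,
strand assignment and an optional batch/status-correlated bias on the logit of
the read-sampling frequency are layered on top, so every downstream stage
(filtering, allele-frequency estimation, PCA diagnostics, association,
burden testing) can be exercised against a known truth table.

Defaults follow a 44-pool design: 24 case pools (eight of 12, one of 18,
fifteen of 24 individuals; 474 cases) and 20 control pools of 24 (480
controls), sequenced in four batches at a mean depth of 1000x per pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])

#: 44-pool default: 8x12 + 1x18 + 15x24 case pools, then 20x24 control pools.
DEFAULT_CASE_POOL_SIZES: tuple[int, ...] = (12,) * 8 + (18,) + (24,) * 15
DEFAULT_CONTROL_POOL_SIZES: tuple[int, ...] = (24,) * 20


def case_frequency(p0: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control frequency and allelic OR.

    Under a multiplicative allelic model,
    ``p_case = p0 * OR / (1 + p0 * (OR - 1))``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be positive, got {odds_ratio}")
    return p0 * odds_ratio / (1.0 + p0 * (odds_ratio - 1.0))


@dataclass(frozen=True)
class MAFSpec:
    """Distribution of control minor-allele frequencies across sites.

    ``kind`` is one of ``point`` (all sites at ``value``), ``uniform``
    (uniform on [low, high]) or ``loguniform`` (log-uniform on [low, high],
    the default for rare-variant-enriched target panels).
    """

    kind: str = "loguniform"
    value: float = 0.05
    low: float = 0.005
    high: float = 0.5

    def validate(self) -> None:
        if self.kind not in {"point", "uniform", "loguniform"}:
            raise ValueError(f"maf_distribution.kind unknown: {self.kind!r}")
        if self.kind == "point":
            if not 0.0 < self.value < 1.0:
                raise ValueError(
                    f"maf_distribution.value must lie in (0, 1), got {self.value}"
                )
        else:
            if not 0.0 < self.low <= self.high < 1.0:
                raise ValueError(
                    "maf_distribution bounds must satisfy 0 < low <= high < 1, "
                    f"got [{self.low}, {self.high}]"
                )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.value)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=n))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated pooled-sequencing experiment."""

    n_case_pools: int = 24
    n_control_pools: int = 20
    pool_sizes: Sequence[int] = DEFAULT_CASE_POOL_SIZES + DEFAULT_CONTROL_POOL_SIZES
    n_batches: int = 4
    n_sites: int = 1000
    maf_distribution: MAFSpec = field(default_factory=MAFSpec)
    mean_depth: float = 1000.0
    depth_dispersion: float = 8.0
    error_rate: float = 1e-3
    strand_imbalance: float = 0.5
    bias_sd: float = 0.0
    causal_sites: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0

    @property
    def n_pools(self) -> int:
        return self.n_case_pools + self.n_control_pools

    def resolved_pool_sizes(self) -> np.ndarray:
        sizes = np.asarray(self.pool_sizes, dtype=int)
        if sizes.size == self.n_pools:
            return sizes
        # short list: cycle, case pools first
        return np.resize(sizes, self.n_pools)

    def validate(self) -> None:
        if self.n_case_pools < 1:
            raise ValueError(f"n_case_pools must be >= 1, got {self.n_case_pools}")
        if self.n_control_pools < 1:
            raise ValueError(
                f"n_control_pools must be >= 1, got {self.n_control_pools}"
            )
        if self.n_batches < 1:
            raise ValueError(f"n_batches must be >= 1, got {self.n_batches}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        sizes = self.resolved_pool_sizes()
        if sizes.size == 0 or (sizes < 1).any():
            raise ValueError(f"pool_sizes must all be >= 1, got {list(self.pool_sizes)}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.depth_dispersion <= 0:
            raise ValueError(
                f"depth_dispersion must be > 0, got {self.depth_dispersion}"
            )
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must lie in [0, 1], got {self.error_rate}")
        if not 0.0 <= self.strand_imbalance <= 1.0:
            raise ValueError(
                f"strand_imbalance must lie in [0, 1], got {self.strand_imbalance}"
            )
        if self.bias_sd < 0:
            raise ValueError(f"bias_sd must be >= 0, got {self.bias_sd}")
        self.maf_distribution.validate()
        seen = set()
        for idx, p0, or_ in self.causal_sites:
            if not 0 <= idx < self.n_sites:
                raise ValueError(
                    f"causal_sites index {idx} out of range for n_sites={self.n_sites}"
                )
            if idx in seen:
                raise ValueError(f"causal_sites indices must be distinct, {idx} repeats")
            seen.add(idx)
            if not 0.0 < p0 < 1.0:
                raise ValueError(f"causal_sites control MAF must lie in (0,1), got {p0}")
            if or_ <= 0:
                raise ValueError(f"causal_sites odds ratio must be > 0, got {or_}")


def _make_manifest(config: SimConfig) -> pd.DataFrame:
    n = config.n_pools
    sizes = config.resolved_pool_sizes()
    status = np.array(
        ["case"] * config.n_case_pools + ["control"] * config.n_control_pools
    )
    # contiguous batch blocks, mimicking sequencing runs
    batch = np.array([f"b{(i * config.n_batches) // n + 1}" for i in range(n)])
    return pd.DataFrame(
        {
            "pool_id": [f"pool{i + 1}" for i in range(n)],
            "status": status,
            "n_individuals": sizes,
            "batch": batch,
        }
    )


def simulate_pool_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate one pooled-sequencing experiment.

    Returns
    -------
    matrix : DataFrame
        Site call matrix with columns ``chrom, pos, ref, allele, pool_id,
        fwd, rev`` (post-quality-filter stranded base-call counts; rows with
        zero total count are omitted).
    manifest : DataFrame
        Pool manifest with columns ``pool_id, status, n_individuals, batch``.
    truth : dict of DataFrame
        ``"sites"``: per site true control/case alternate-allele frequencies;
        ``"pools"``: per site x pool true alternate-chromosome count among
        ``2N``.

    The sampling chain per site and pool: true alternate chromosomes
    ``k ~ Binomial(2N, p_group)``; depth ``D ~ NegBin(mean_depth,
    depth_dispersion)``; reads sample chromosomes uniformly, so alternate
    reads are ``Binomial(D, f)`` with ``f = k/2N`` (optionally logit-shifted
    by the batch/status bias); each base call miscalls with ``error_rate`` to
    a uniformly chosen other base; each call lands on the forward strand with
    probability ``strand_imbalance``.  Fully deterministic given
    ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_maf, rng_geno, rng_depth, rng_reads, rng_err, rng_strand = rngs

    manifest = _make_manifest(config)
    sizes = manifest["n_individuals"].to_numpy()
    is_case = (manifest["status"] == "case").to_numpy()
    S, P = config.n_sites, config.n_pools

    p_control = config.maf_distribution.sample(S, rng_maf)
    p_case = p_control.copy()
    for idx, p0, or_ in config.causal_sites:
        p_control[idx] = p0
        p_case[idx] = case_frequency(p0, or_)

    ref_idx = rng_maf.integers(0, 4, size=S)
    alt_off = rng_maf.integers(1, 4, size=S)
    alt_idx = (ref_idx + alt_off) % 4

    p_group = np.where(is_case[None, :], p_case[:, None], p_control[:, None])  # S x P
    two_n = (2 * sizes)[None, :]
    k_true = rng_geno.binomial(np.broadcast_to(two_n, (S, P)), p_group)

    nb_k = config.depth_dispersion
    nb_p = nb_k / (nb_k + config.mean_depth)
    depth = rng_depth.negative_binomial(nb_k, nb_p, size=(S, P))

    f = k_true / two_n
    if config.bias_sd > 0:
        batches = manifest["batch"].to_numpy()
        batch_codes, batch_levels = pd.factorize(batches)
        delta_batch = rng_reads.normal(0.0, config.bias_sd, size=(S, len(batch_levels)))
        delta_status = rng_reads.normal(0.0, config.bias_sd, size=S)
        shift = delta_batch[:, batch_codes] + delta_status[:, None] * is_case[None, :]
        interior = (f > 0) & (f < 1)
        f_safe = np.clip(f, 1e-12, 1 - 1e-12)
        logit = np.log(f_safe / (1 - f_safe))
        f = np.where(interior, 1.0 / (1.0 + np.exp(-(logit + shift))), f)

    alt_reads = rng_reads.binomial(depth, f)
    ref_reads = depth - alt_reads

    counts = np.zeros((S, P, 4), dtype=np.int64)
    if config.error_rate > 0:
        ref_err = rng_err.binomial(ref_reads, config.error_rate)
        alt_err = rng_err.binomial(alt_reads, config.error_rate)
        thirds = np.full(3, 1.0 / 3.0)
        ref_err_split = rng_err.multinomial(ref_err, thirds)  # S x P x 3
        alt_err_split = rng_err.multinomial(alt_err, thirds)
        ref_reads = ref_reads - ref_err
        alt_reads = alt_reads - alt_err
        others = np.array([[b for b in range(4) if b != a] for a in range(4)])
        site_rows = np.arange(S)[:, None, None]
        pool_cols = np.arange(P)[None, :, None]
        np.add.at(
            counts, (site_rows, pool_cols, others[ref_idx][:, None, :]), ref_err_split
        )
        np.add.at(
            counts, (site_rows, pool_cols, others[alt_idx][:, None, :]), alt_err_split
        )
    counts[np.arange(S), :, ref_idx] += ref_reads
    counts[np.arange(S), :, alt_idx] += alt_reads

    fwd = rng_strand.binomial(counts, config.strand_imbalance)
    rev = counts - fwd

    s_ix, p_ix, a_ix = np.nonzero(counts)
    matrix = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": s_ix + 1,
            "ref": BASES[ref_idx[s_ix]],
            "allele": BASES[a_ix],
            "pool_id": manifest["pool_id"].to_numpy()[p_ix],
            "fwd": fwd[s_ix, p_ix, a_ix],
            "rev": rev[s_ix, p_ix, a_ix],
        }
    )

    truth_sites = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": np.arange(1, S + 1),
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
            "p_control": p_control,
            "p_case": p_case,
        }
    )
    pool_grid, site_grid = np.meshgrid(np.arange(P), np.arange(S))
    truth_pools = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": site_grid.ravel() + 1,
            "pool_id": manifest["pool_id"].to_numpy()[pool_grid.ravel()],
            "alt_count": k_true.ravel(),
            "n_chrom": np.broadcast_to(two_n, (S, P)).ravel(),
        }
    )
    return matrix, manifest, {"sites": truth_sites, "pools": truth_pools}


def simulate_individual_genotypes(
    n_case: int,
    n_control: int,
    p0: float,
    or_: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Individual-level 2x3 genotype counts under HWE within each group.

    The case allele frequency is derived from the control frequency ``p0``
    and the allelic odds ratio ``or_`` under the multiplicative model.
    Columns are homozygous-major / heterozygous / homozygous-minor counts.
    """
    if n_case < 1:
        raise ValueError(f"n_case must be >= 1, got {n_case}")
    if n_control < 1:
        raise ValueError(f"n_control must be >= 1, got {n_control}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if or_ <= 0:
        raise ValueError(f"or_ must be > 0, got {or_}")
    rng = np.random.default_rng(seed)
    p1 = case_frequency(p0, or_)
    rows = []
    for group, n, p in (("case", n_case, p1), ("control", n_control, p0)):
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        aa, ab, bb = rng.multinomial(n, probs)
        rows.append({"group": group, "n_AA": aa, "n_Aa": ab, "n_aa": bb})
    return pd.DataFrame(rows).set_index("group")
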