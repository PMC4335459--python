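"""End-to-end pipeline driver.

Runs filter -> allele frequencies -> PCA / outlier pools -> SNV exclusions ->
pool regression -> genomic control -> overdispersion QC -> gene burden, and
writes every stage table plus a machine-readable run report (lambda, excluded
pools, SNV counts at each stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io
from .afreq import estimate_pool_af, pivot_af_matrix
from .association import (
    apply_genomic_control,
    associate_snvs,
    build_association_data,
    exclude_snvs,
    overdispersion_qc,
)
from .burden import gene_burden_scan
from .filters import FilterThresholds, filter_experiment
from .pca import compute_pca, flag_outlier_pools, standardize_af_matrix


@dataclass
class RunConfig:
    """Pipeline thresholds and options; defaults are the method's constants."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    overdispersion_p: float = 1.5e-5
    outlier_mads: float = 4.0
    pca_axes: int = 2
    n_permutations: int = 0
    permute_if_p_below: float = 1.0
    functional_only: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        thr = raw.pop("thresholds", {})
        return cls(thresholds=FilterThresholds(**thr), **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    config: RunConfig = RunConfig(),
    gene_map: pd.DataFrame | None = None,
    bed: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis; returns a bundle of stage outputs.

    The bundle maps stage names to DataFrames plus a ``report`` dict with
    lambda, excluded pools and the SNV counts funnel.  When ``out_dir`` is
    given every table is written as TSV and the report as JSON.
    """
    stage = "filter"
    try:
        if bed is not None:
            matrix = io.restrict_to_regions(matrix, bed)
        retained, verdicts = filter_experiment(matrix, manifest, config.thresholds)

        stage = "allele_frequency"
        af_table = estimate_pool_af(matrix, retained, manifest)

        stage = "pca"
        outliers: list[str] = []
        pca_scores = None
        af_matrix = pivot_af_matrix(af_table) if not af_table.empty else None
        if af_matrix is not None and af_matrix.shape[0] >= 2:
            standardized = standardize_af_matrix(af_matrix)
            if standardized.shape[0] >= 1:
                k = min(config.pca_axes, af_matrix.shape[1] - 1)
                pca = compute_pca(standardized, k=k)
                outliers = flag_outlier_pools(pca.scores, config.outlier_mads)
                pca_scores = pca.scores

        stage = "association"
        data = build_association_data(af_table, manifest, tuple(outliers))
        assoc = associate_snvs(data)
        assoc = exclude_snvs(assoc, af_table, tuple(outliers))

        stage = "genomic_control"
        analysis = assoc[~assoc["excluded"]].reset_index(drop=True)
        analysis, lambda_gc = apply_genomic_control(analysis)

        stage = "overdispersion_qc"
        analysis = overdispersion_qc(analysis, config.overdispersion_p)
        clean = analysis[~analysis["overdispersed"]].reset_index(drop=True)

        stage = "burden"
        burden = None
        if gene_map is not None and not clean.empty:
            burden = gene_burden_scan(
                clean,
                gene_map,
                data=data,
                functional_only=config.functional_only,
                n_permutations=config.n_permutations,
                seed=config.seed,
                permute_if_p_below=config.permute_if_p_below,
            )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "lambda_gc": lambda_gc,
        "excluded_pools": outliers,
        "funnel": {
            "candidate_alleles": int(
                verdicts[["chrom", "pos", "allele"]].drop_duplicates().shape[0]
            ),
            "retained_variants": int(len(retained)),
            "tested_snvs": int(len(assoc)),
            "post_exclusion_snvs": int(len(analysis)),
            "post_overdispersion_snvs": int(len(clean)),
        },
        "config": config.to_dict(),
    }
    bundle = {
        "retained": retained,
        "verdicts": verdicts,
        "af_table": af_table,
        "pca_scores": pca_scores,
        "associations": assoc,
        "analysis": analysis,
        "clean": clean,
        "burden": burden,
        "association_data": data,
        "report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_table(retained, out / "retained_variants.tsv")
        io.write_table(
            af_table, out / "pool_allele_frequencies.tsv"
        )
        if pca_scores is not None:
            io.write_table(pca_scores.reset_index(names="pool_id"), out / "pca_scores.tsv")
        io.write_table(assoc, out / "snv_associations_raw.tsv")
        io.write_table(analysis, out / "snv_associations.tsv")
        io.write_table(clean, out / "snv_associations_clean.tsv")
        if burden is not None:
            io.write_table(burden, out / "gene_burden.tsv")
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return bundle
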