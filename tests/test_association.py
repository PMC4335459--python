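"""Tests for the per-SNV pool regression, genomic control and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix
from poolassoc.afreq import estimate_pool_af
from poolassoc.association import (
    AssociationData,
    apply_genomic_control,
    associate_snvs,
    build_association_data,
    exclude_snvs,
    overdispersion_qc,
    snv_pool_regression,
)
from poolassoc.filters import filter_experiment
from poolassoc.pipeline import run_pipeline
from poolassoc.simulate import MAFSpec, SimConfig, case_frequency, simulate_pool_experiment


def test_equal_frequencies_give_null_chi2():
    ecc = np.full(8, 12.0)
    total = np.full(8, 48.0)
    status = np.array(["case"] * 4 + ["control"] * 4)
    chi2, direction, dev, dof = snv_pool_regression(ecc, total, status)
    assert chi2 <= 1e-6
    assert direction == 0
    assert dof == 6


def test_one_pool_per_group_equals_2x2_likelihood_ratio_oracle():
    # independent oracle: G-test on the rounded chromosome counts
    s = np.array([9.0, 3.0])
    t = np.array([48.0, 48.0])
    status = np.array(["case", "control"])
    chi2, direction, dev, dof = snv_pool_regression(s, t, status)
    table = [[9, 48 - 9], [3, 48 - 3]]
    g, p, _, _ = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
    assert chi2 == pytest.approx(g, rel=1e-10)
    assert direction == 1
    assert dev == pytest.approx(0.0, abs=1e-10)
    assert dof == 0


def test_regression_matches_statsmodels_glm_oracle(rng):
    sm = pytest.importorskip("statsmodels.api")
    t = rng.integers(20, 50, size=12).astype(float)
    s = rng.binomial(t.astype(int), 0.25).astype(float)
    status = np.array(["case"] * 6 + ["control"] * 6)
    chi2, _, dev, dof = snv_pool_regression(s, t, status)
    X = sm.add_constant((status == "case").astype(float))
    fit = sm.GLM(
        np.column_stack([s, t - s]), X, family=sm.families.Binomial()
    ).fit()
    assert chi2 == pytest.approx(fit.null_deviance - fit.deviance, rel=1e-8)
    assert dev == pytest.approx(fit.deviance, rel=1e-8)
    assert dof == int(fit.df_resid)


def test_regression_requires_both_groups_and_two_pools():
    with pytest.raises(ValueError, match="case and one control"):
        snv_pool_regression([5, 6], [48, 48], np.array(["case", "case"]))
    with pytest.raises(ValueError, match="2 pools"):
        snv_pool_regression([5], [48], np.array(["case"]))


def test_planted_effect_matches_noncentral_chi2_oracle(rng):
    """Median chi2 of a planted OR=2.5, MAF 5% variant tracks the analytic
    noncentral expectation for the total chromosome counts."""
    p0 = 0.05
    p1 = case_frequency(p0, 2.5)
    n_case, n_ctrl, two_n, depth = 42, 40, 48, 1000
    m1, m0 = n_case * two_n, n_ctrl * two_n
    ncp = (p1 - p0) ** 2 / (p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
    expected_median = stats.ncx2.median(1, ncp)
    status = np.array(["case"] * n_case + ["control"] * n_ctrl)
    totals = np.full(n_case + n_ctrl, float(two_n))
    chis = []
    for _ in range(200):
        k = rng.binomial(two_n, np.where(np.arange(82) < n_case, p1, p0))
        f = rng.binomial(depth, k / two_n) / depth
        chi2, _, _, _ = snv_pool_regression(f * two_n, totals, status)
        chis.append(chi2)
    assert np.median(chis) == pytest.approx(expected_median, rel=0.15)


def _af_table_from_rows(rows, manifest, retained):
    return estimate_pool_af(make_matrix(rows), retained, manifest)


def test_exclusion_rules(toy_manifest):
    # variant A: minor allele only in cases -> zero count in controls
    # variant B: minor allele only in pools p3 (excluded) -> only in excluded pools
    # variant C: present in both groups -> retained
    rows = []
    for pos, alt_pools in [(1, ["p1", "p2"]), (2, ["p3"]), (3, ["p1", "p4"])]:
        for p in ["p1", "p2", "p3", "p4", "p5", "p6"]:
            rows.append(("chr1", pos, "A", "A", p, 450, 450))
        for p in alt_pools:
            rows.append(("chr1", pos, "A", "G", p, 50, 50))
    retained = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [1, 2, 3], "ref": ["A"] * 3, "alt": ["G"] * 3}
    )
    af_table = _af_table_from_rows(rows, toy_manifest, retained)
    data = build_association_data(af_table, toy_manifest, excluded_pools=("p3",))
    assoc = associate_snvs(data)
    out = exclude_snvs(assoc, af_table, excluded_pools=("p3",)).set_index("pos")
    assert out.loc[1, "excluded"]
    assert out.loc[1, "exclusion_reason"] == "zero count in case or controls"
    assert out.loc[2, "excluded"]
    assert out.loc[2, "exclusion_reason"] == "only in excluded pools"
    assert not out.loc[3, "excluded"]


def test_genomic_control_correction_and_clamp():
    assoc = pd.DataFrame(
        {
            "chrom": "c",
            "pos": range(5),
            "chi2": [10.83, 0.2, 0.5, 0.9, 0.3],
            "excluded": False,
        }
    )
    corrected, lam = apply_genomic_control(assoc, lambda_gc=1.3)
    assert lam == pytest.approx(1.3)
    assert corrected.loc[0, "chi2_gc"] == pytest.approx(10.83 / 1.3, rel=1e-9)
    # chi2_1 survival at 8.33
    assert corrected.loc[0, "p_gc"] == pytest.approx(3.9e-3, rel=0.02)
    # deflation clamp
    _, lam_clamped = apply_genomic_control(assoc, lambda_gc=0.7)
    assert lam_clamped == 1.0


def test_corrected_median_equals_chi2_median_by_construction(rng):
    chi2 = rng.chisquare(1, 4001) * 1.4
    assoc = pd.DataFrame({"chi2": chi2, "excluded": False})
    corrected, lam = apply_genomic_control(assoc)
    assert lam > 1
    from poolassoc.pca import CHI2_1_MEDIAN

    assert np.median(corrected["chi2_gc"]) == pytest.approx(CHI2_1_MEDIAN, rel=1e-9)


def test_overdispersed_snv_flagged_and_degenerate_dof_skipped(rng):
    """A SNV with strong pool-specific logit jitter fails the residual-deviance
    QC; detection rate rises with the jitter SD."""
    n_pools, two_n, depth = 80, 48, 1000
    status = np.array(["case"] * 40 + ["control"] * 40)

    def one_dev(sd):
        logit = np.log(0.3 / 0.7) + rng.normal(0, sd, n_pools)
        p = 1 / (1 + np.exp(-logit))
        k = rng.binomial(two_n, p)
        f = rng.binomial(depth, k / two_n) / depth
        _, _, dev, dof = snv_pool_regression(f * two_n, np.full(n_pools, two_n), status)
        return dev, dof

    crit = stats.chi2.isf(1.5e-5, n_pools - 2)
    hits = {sd: np.mean([one_dev(sd)[0] > crit for _ in range(60)]) for sd in (0.0, 0.5)}
    assert hits[0.0] <= 0.05
    assert hits[0.5] >= 0.9

    assoc = pd.DataFrame(
        {"residual_deviance": [0.0, 500.0], "resid_dof": [10, 0], "chi2": [0.1, 0.2]}
    )
    out = overdispersion_qc(assoc)
    assert not out.loc[0, "overdispersed"]
    assert not out.loc[1, "overdispersed"]  # dof <= 0: QC skipped


def test_direction_agrees_with_group_frequency_difference(small_null_experiment):
    _, matrix, manifest, _ = small_null_experiment
    retained, _ = filter_experiment(matrix, manifest)
    af_table = estimate_pool_af(matrix, retained, manifest)
    data = build_association_data(af_table, manifest)
    assoc = associate_snvs(data)
    nonnull = assoc[assoc["chi2"] > 0]
    f_case = nonnull["minor_case"] / nonnull["total_case"]
    f_ctrl = nonnull["minor_control"] / nonnull["total_control"]
    assert (nonnull["direction"] == np.sign(f_case - f_ctrl)).all()


def test_bias_inflates_lambda_and_gc_restores_type_i_error():
    cfg = SimConfig(
        n_sites=2500,
        seed=77,
        bias_sd=0.05,
        maf_distribution=MAFSpec("uniform", low=0.02, high=0.5),
    )
    matrix, manifest, _ = simulate_pool_experiment(cfg)
    bundle = run_pipeline(matrix, manifest)
    lam = bundle["report"]["lambda_gc"]
    assert lam > 1.2
    clean = bundle["clean"]
    type_i = (clean["p_gc"] < 0.05).mean()
    assert 0.03 <= type_i <= 0.08
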