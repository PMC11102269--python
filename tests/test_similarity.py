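"""Overlap similarity and regression fits: hypergeometric scoring against a
combinatorial oracle, permutation-test contracts, PC1 extraction, and the
per-group RMSE machinery."""

import math

import numpy as np
import pandas as pd
import pytest

import prgbm
from prgbm.similarity import (
    LinearFit,
    fit_pr_line,
    group_rmse,
    group_rmse_null,
    paired_trom_null,
    sample_pc1,
    trom_from_sets,
    trom_scores,
)


def _assoc(sets, n_genes):
    genes = [f"g{i}" for i in range(n_genes)]
    A = pd.DataFrame(False, index=genes, columns=list(sets))
    for name, idx in sets.items():
        A.loc[[f"g{i}" for i in idx], name] = True
    return A


def test_identical_sets_match_combinatorial_oracle():
    """Two samples sharing one 10-gene set in a 100-gene universe: the
    upper-tail overlap probability is exactly 1/C(100,10)."""
    idx = list(range(10))
    trom = trom_from_sets(_assoc({"a": idx, "b": idx}, 100))
    p_exact = 1.0 / math.comb(100, 10)
    # three unique sample pairs share the same p -> BH leaves them unchanged
    expected_score = -np.log10(p_exact)
    assert np.allclose(trom.scores.loc["a", "b"], expected_score, rtol=1e-10)
    assert np.allclose(trom.scores.to_numpy(), trom.scores.to_numpy().T)


def test_partial_overlap_matches_enumeration_oracle():
    """Brute-force enumeration of the hypergeometric upper tail reproduces the
    pre-adjustment overlap p to 1e-10."""
    from scipy.stats import hypergeom

    n_genes, k1, k2, m = 40, 8, 6, 3
    p_impl = hypergeom.sf(m - 1, n_genes, k1, k2)
    p_brute = sum(
        math.comb(k1, j) * math.comb(n_genes - k1, k2 - j) / math.comb(n_genes, k2)
        for j in range(m, min(k1, k2) + 1)
    )
    assert abs(p_impl - p_brute) < 1e-10


def test_disjoint_sets_score_zero_and_self_overlap_maximal():
    trom = trom_from_sets(_assoc({"a": range(10), "b": range(10, 20)}, 100))
    assert trom.scores.loc["a", "b"] < 1e-6
    big = trom_from_sets(
        _assoc({"a": range(10), "b": range(5, 15), "c": range(50, 60)}, 100)
    )
    row = big.scores.loc["a"]
    assert row.idxmax() == "a"


def test_trom_invariant_under_gene_relabeling(adjusted):
    expr = adjusted["resid_patient"]
    base = trom_scores(expr)
    rng = np.random.default_rng(1)
    perm = rng.permutation(expr.values.index)
    relabeled = prgbm.ExpressionMatrix(
        expr.values.loc[perm].set_axis([f"x{i}" for i in range(len(perm))]),
        stage="residual",
    )
    out = trom_scores(relabeled)
    assert np.allclose(base.scores.to_numpy(), out.scores.to_numpy(), atol=1e-12)


def test_paired_trom_null_detects_pair_baseline(drift_cohort, adjusted):
    trom = trom_scores(adjusted["resid_patient"])
    res = paired_trom_null(trom, drift_cohort.cohort, n_perm=2000, seed=5)
    assert res.pvalue <= 0.001
    # bit-exact reproducibility for a fixed seed
    res2 = paired_trom_null(trom, drift_cohort.cohort, n_perm=2000, seed=5)
    assert res.pvalue == res2.pvalue and res.null_mean == res2.null_mean


def test_paired_trom_null_contracts(drift_cohort, adjusted):
    trom = trom_scores(adjusted["resid_patient"])
    with pytest.raises(ValueError):
        paired_trom_null(trom, drift_cohort.cohort, n_perm=0)


def test_sample_pc1_centering_sign_and_recovery(rng):
    # two samples: centered scores are symmetric about zero
    two = prgbm.ExpressionMatrix(
        pd.DataFrame(rng.normal(size=(30, 2)), index=[f"g{i}" for i in range(30)],
                     columns=["a", "b"]),
        stage="residual",
    )
    s = sample_pc1(two)
    assert np.isclose(s.sum(), 0.0, atol=1e-10)

    # planted rank-1 structure is recovered up to sign
    factor = rng.normal(size=40)
    loadings = rng.normal(size=25)
    X = np.outer(loadings, factor) + 0.05 * rng.normal(size=(25, 40))
    expr = prgbm.ExpressionMatrix(
        pd.DataFrame(X, index=[f"g{i}" for i in range(25)],
                     columns=[f"s{i}" for i in range(40)]),
        stage="residual",
    )
    scores = sample_pc1(expr)
    assert abs(np.corrcoef(scores, factor)[0, 1]) > 0.99

    # permuting sample order permutes scores identically
    perm = rng.permutation(expr.values.columns)
    scores_perm = sample_pc1(prgbm.ExpressionMatrix(expr.values[perm], stage="residual"))
    pd.testing.assert_series_equal(scores.loc[perm], scores_perm, check_names=False)


def test_fit_pr_line_trivial_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    fit = fit_pr_line(x, x)
    assert np.isclose(fit.beta0, 0.0, atol=1e-12) and np.isclose(fit.beta1, 1.0)
    flat = fit_pr_line(x, np.full(4, 2.0))
    assert np.isclose(flat.beta1, 0.0, atol=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        fit_pr_line(np.ones(4), x)


def test_group_rmse_closed_forms_and_decomposition(rng):
    x = rng.normal(size=20)
    y = 0.5 + 0.8 * x + rng.normal(size=20)
    fit = fit_pr_line(x, y)
    on_line = fit.predict(x[:5])
    assert group_rmse(fit, x[:5], on_line) == 0.0
    # residuals (1, -2) about the line -> sqrt(2.5)
    xs = x[:2]
    ys = fit.predict(xs) + np.array([1.0, -2.0])
    assert np.isclose(group_rmse(fit, xs, ys), np.sqrt(2.5))
    # subset = full cohort equals the fit's global residual RMSE
    assert np.isclose(group_rmse(fit, x, y), np.sqrt((fit.residuals**2).mean()))
    # weighted mean of squared group RMSEs over a partition = global MSE
    idx = np.arange(20)
    parts = [idx[:7], idx[7:12], idx[12:]]
    weighted = sum(len(p) * group_rmse(fit, x[p], y[p]) ** 2 for p in parts) / 20
    assert np.isclose(weighted, (fit.residuals**2).mean())


def test_group_rmse_null_whole_cohort_degenerate(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    fit = fit_pr_line(x, y)
    obs = group_rmse(fit, x, y)
    res = group_rmse_null(fit, "all", 30, obs, n_perm=200, seed=1)
    assert res.pvalue == 1.0  # every null replicate equals the observed value
    with pytest.raises(ValueError):
        group_rmse_null(fit, "all", 31, obs, n_perm=10)


def test_strong_drift_pc1_fit_tightest_for_short_ttr():
    """With strong TTR-dependent drift the short-TTR group hugs the P-R
    regression line: its RMSE beats the long-TTR group's and its permutation
    p is < 0.05, in >= 80% of seeds."""
    ordered = significant = 0
    n_seeds = 5
    for seed in range(n_seeds):
        c = prgbm.generate_cohort(
            prgbm.SimulationConfig(
                n_pairs=150, n_genes=300, n_drift_genes=150,
                sigma_drift_per_month=0.6, program_decay_per_month=0.2,
                seed=7000 + seed,
            )
        )
        merged = prgbm.ExpressionMatrix(
            pd.concat([c.tpm_primary.values, c.tpm_recurrent.values], axis=1), "tpm"
        )
        design = prgbm.CovariateDesign.from_cohort(c.cohort)
        resid = prgbm.regress_out(
            prgbm.log_transform(merged), design, ["age", "gender", "data_source"]
        )
        _, stats_, _ = prgbm.expression_pc1_fit(resid, c.cohort, n_perm=500, seed=seed)
        by_group = {s.ttr_group: s for s in stats_}
        ordered += by_group["le6"].rmse < by_group["gt12"].rmse
        significant += by_group["le6"].pvalue < 0.05
    assert ordered >= 4
    assert significant >= 4


def test_tmb_pr_fit_identity_line():
    n = 12
    frame = pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(n)],
            "patient_id": [f"PT{i}" for i in range(n)],
            "sample_id_primary": [f"P{i}_P" for i in range(n)],
            "sample_id_recurrent": [f"P{i}_R" for i in range(n)],
            "age": 60.0, "gender": "f", "data_source": "x",
            "ttr": np.linspace(2, 30, n), "pfi": np.linspace(2, 30, n),
            "event": 1, "idh_status": "IDHwt", "mgmt_status": "methylated",
            "tmz_treated": 1, "extent_of_resection": "total",
        }
    )
    cohort = prgbm.CohortTable(frame)
    base = np.linspace(1, 5, n)
    tmb = prgbm.TmbTable(
        pd.DataFrame(
            {"sample_id": list(cohort.primary_ids) + list(cohort.recurrent_ids),
             "tmb": np.r_[base, base]}
        )
    )
    fit, stats_ = prgbm.tmb_pr_fit(tmb, cohort, n_perm=100, seed=0)
    assert np.isclose(fit.beta1, 1.0) and np.isclose(fit.beta0, 0.0, atol=1e-10)
    assert all(np.isclose(s.rmse, 0.0) for s in stats_ if not np.isnan(s.rmse))
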