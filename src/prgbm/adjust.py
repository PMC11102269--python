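"""Expression preprocessing: presence filter, log transform, covariate scan,
and regression-based covariate removal.

The covariate model is the per-gene ordinary linear model
``log2(TPM+1) ~ intercept + covariates`` with categorical covariates encoded
as treatment dummies (reference = first level in lexical order).  Residuals
of that model are the "adjusted" expression used by every downstream stage.

Pair identity enters the design as one dummy per pair.  Any covariate that is
constant within pairs (age, gender, data source, TTR) is linearly aliased
with the pair dummies; such covariates are therefore tested in the model
without the pair block (logged), while progression status and the pair block
itself are tested in the full model.  Residual extraction uses a
pseudoinverse projection, which is well-defined under the aliasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, ExpressionMatrix

logger = logging.getLogger(__name__)

SIX_COVARIATES = ("progression_status", "ttr", "age", "gender", "data_source", "pair_id")
ADJUSTMENT_COVARIATES = ("age", "gender", "data_source", "pair_id")


def filter_expressed(tpm: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes with TPM > 0 in strictly more than ``min_fraction`` of samples."""
    if tpm.stage != "tpm":
        raise ValueError(f"filter_expressed expects a TPM matrix, got stage {tpm.stage!r}")
    frac = (tpm.values.to_numpy() > 0).mean(axis=1)
    keep = frac > min_fraction
    if not keep.any():
        raise ValueError("presence filter removed every gene")
    return ExpressionMatrix(tpm.values.loc[keep], stage="tpm")


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if tpm.stage != "tpm":
        raise ValueError(f"log_transform expects a TPM matrix, got stage {tpm.stage!r}")
    return ExpressionMatrix(np.log2(tpm.values + 1.0), stage="log2p1")


@dataclass
class CovariateDesign:
    """Per-sample covariate values plus dummy-encoded design matrices.

    ``table`` has one row per sample (both pair members) with columns
    progression_status, ttr, age, gender, data_source, pair_id.
    """

    table: pd.DataFrame

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "CovariateDesign":
        t = cohort.table
        rows = []
        for _, r in t.iterrows():
            for status, sid in (("primary", r.sample_id_primary), ("recurrent", r.sample_id_recurrent)):
                rows.append(
                    {
                        "sample_id": sid,
                        "progression_status": status,
                        "ttr": r.ttr,
                        "age": r.age,
                        "gender": r.gender,
                        "data_source": r.data_source,
                        "pair_id": r.pair_id,
                    }
                )
        return cls(pd.DataFrame(rows).set_index("sample_id"))

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def block(self, covariate: str) -> np.ndarray:
        """Dummy-encoded columns for one covariate (no intercept column)."""
        if covariate not in self.table.columns:
            raise KeyError(f"unknown covariate {covariate!r}")
        col = self.table[covariate]
        if covariate in ("ttr", "age"):
            return col.to_numpy(dtype=float)[:, None]
        levels = sorted(pd.unique(col.astype(str)))
        # treatment coding, reference = first lexical level
        return np.column_stack(
            [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
        ) if len(levels) > 1 else np.zeros((len(col), 0))

    def matrix(self, covariates: list[str]) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Design matrix (with intercept) and (covariate, n_columns) blocks."""
        parts = [np.ones((len(self.table), 1))]
        blocks = [("intercept", 1)]
        for cov in covariates:
            b = self.block(cov)
            parts.append(b)
            blocks.append((cov, b.shape[1]))
        return np.hstack(parts), blocks

    def is_pair_level(self, covariate: str) -> bool:
        """True if the covariate never varies within a pair."""
        if covariate == "pair_id":
            return False
        g = self.table.groupby("pair_id")[covariate].nunique(dropna=False)
        return bool((g <= 1).all())


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of each row of Y on X via pseudoinverse projection."""
    beta = np.linalg.pinv(X) @ Y.T
    return Y - (X @ beta).T


def regress_out(
    expr: ExpressionMatrix, design: CovariateDesign, covariates: list[str] | None = None
) -> ExpressionMatrix:
    """Per-gene OLS residuals of log expression on the covariate design.

    The default covariate set (age, gender, data source, pair identity) is the
    standard adjustment for paired designs.  A rank-deficient design (e.g.
    pair-level covariates alongside the pair block) is tolerated: residuals
    are the projection onto the design's column space, unique regardless of
    aliasing; aliased covariates are reported in a warning.
    """
    if expr.stage not in ("log2p1", "residual"):
        raise ValueError(f"regress_out expects log2p1 expression, got stage {expr.stage!r}")
    covariates = list(covariates if covariates is not None else ADJUSTMENT_COVARIATES)
    missing = [s for s in expr.sample_ids if s not in design.sample_ids]
    if missing:
        raise ValueError(f"design lacks samples: {missing[:5]}")
    sub = CovariateDesign(design.table.loc[list(expr.sample_ids)])
    X, blocks = sub.matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_blocks(sub, covariates)
        logger.info(
            "design is rank-deficient (rank %d of %d columns); aliased covariates: %s; "
            "residuals computed by projection",
            rank,
            X.shape[1],
            aliased,
        )
    resid = _residualize(expr.values.to_numpy(dtype=float), X)
    return ExpressionMatrix(
        pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids), stage="residual"
    )


def _aliased_blocks(design: CovariateDesign, covariates: list[str]) -> list[str]:
    """Covariates whose block adds no rank given the *other* blocks."""
    full, _ = design.matrix(covariates)
    r_full = np.linalg.matrix_rank(full)
    aliased = []
    for cov in covariates:
        others, _ = design.matrix([c for c in covariates if c != cov])
        if np.linalg.matrix_rank(others) == r_full:
            aliased.append(cov)
    return aliased


@dataclass
class CovariateScanResult:
    """Per-covariate impact on expression at FDR < 0.05."""

    proportions: pd.Series
    pvalues: pd.DataFrame  # genes x covariates
    fdr: pd.DataFrame
    notes: dict


def covariate_effect_scan(
    expr: ExpressionMatrix, design: CovariateDesign, alpha: float = 0.05
) -> CovariateScanResult:
    """Partial F-test of each of the six covariates against every gene.

    Each covariate's block is tested against the model containing the other
    covariates; pair-level covariates (aliased with the pair block) are
    tested in the model without pair identity, which is recorded in
    ``notes``.  P-values are BH-adjusted per covariate across genes, and the
    reported proportion is the fraction of genes with FDR < ``alpha``.
    """
    if expr.stage not in ("log2p1", "residual"):
        raise ValueError("covariate scan expects log2p1 expression")
    sub = CovariateDesign(design.table.loc[list(expr.sample_ids)])
    Y = expr.values.to_numpy(dtype=float)
    n = Y.shape[1]

    pvals = {}
    notes = {}
    for cov in SIX_COVARIATES:
        others = [c for c in SIX_COVARIATES if c != cov]
        if sub.is_pair_level(cov):
            others = [c for c in others if c != "pair_id"]
            notes[cov] = "tested without the pair block (pair-level covariate)"
        X_full, _ = sub.matrix(others + [cov])
        X_red, _ = sub.matrix(others)
        r_full = np.linalg.matrix_rank(X_full)
        r_red = np.linalg.matrix_rank(X_red)
        df1 = r_full - r_red
        df2 = n - r_full
        if df1 <= 0 or df2 <= 0:
            raise ValueError(
                f"covariate {cov!r} is not estimable (df1={df1}, df2={df2}); "
                "its block is collinear with the adjustment model"
            )
        rss_full = (_residualize(Y, X_full) ** 2).sum(axis=1)
        rss_red = (_residualize(Y, X_red) ** 2).sum(axis=1)
        F = ((rss_red - rss_full) / df1) / np.maximum(rss_full / df2, 1e-300)
        pvals[cov] = stats.f.sf(F, df1, df2)

    pdf = pd.DataFrame(pvals, index=expr.gene_ids)
    fdr = pdf.apply(lambda col: pd.Series(bh_fdr(col.to_numpy()), index=col.index))
    proportions = (fdr < alpha).mean(axis=0)
    return CovariateScanResult(proportions=proportions, pvalues=pdf, fdr=fdr, notes=notes)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Returns monotone adjusted values: ``adj[i] = min_{j: p_j >= p_i} p_j*m/rank_j``
    clipped at 1.  NaN inputs are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any():
        raise ValueError("bh_fdr: NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("bh_fdr: p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
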