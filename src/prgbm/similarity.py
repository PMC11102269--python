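"""Transcriptome-overlap similarity and primary–recurrent regression fits.

Two complementary views of how similar matched tumor pairs are:

* **TROM scores** — each sample gets an associated-gene set (genes whose
  within-gene z-score for that sample exceeds a threshold); the similarity of
  two samples is ``-log10`` of the BH-adjusted upper-tail hypergeometric
  p-value of their set overlap, capped at 300.  A random re-pairing
  permutation null asks whether true pairs are more similar than chance.

* **PC1 / TMB regression** — each sample is summarized by its score on the
  first principal component (or its TMB); recurrent values are regressed on
  primary values by OLS, and per-TTR-group fit quality (RMSE about the global
  line) is compared against random same-size pair subsets.

Permutation p-values use the add-one estimator ``(1 + k) / (1 + N)`` and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import bh_fdr
from .io import CohortTable, ExpressionMatrix, TmbTable, TTR_GROUPS

logger = logging.getLogger(__name__)

TROM_SCORE_CAP = 300.0


@dataclass
class TromMatrix:
    """Symmetric sample × sample overlap scores."""

    scores: pd.DataFrame
    z_threshold: float
    set_sizes: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index


def trom_scores(expr: ExpressionMatrix, z_threshold: float = 1.5) -> TromMatrix:
    """Transcriptome-overlap scores between all sample pairs.

    A gene is associated with a sample when its within-gene z-score (across
    samples) in that sample exceeds ``z_threshold``.  For each sample pair the
    overlap of associated sets is scored by the upper-tail hypergeometric
    p-value given the two set sizes and the gene universe, BH-adjusted across
    all unique sample pairs, as ``-log10`` capped at 300.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    V = expr.values.to_numpy(dtype=float)
    mean = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (V - mean) / sd, 0.0)
    assoc = pd.DataFrame(z > z_threshold, index=expr.gene_ids, columns=expr.sample_ids)
    return trom_from_sets(assoc, z_threshold=z_threshold)


def trom_from_sets(assoc: pd.DataFrame, z_threshold: float = float("nan")) -> TromMatrix:
    """Overlap scores from an explicit boolean gene × sample association matrix.

    ``trom_scores`` derives the associations from z-scores; this entry point
    accepts any set definition and performs the hypergeometric/BH scoring.
    """
    A = assoc.to_numpy(dtype=bool)
    sizes = A.sum(axis=0)
    empty = np.flatnonzero(sizes == 0)
    if empty.size:
        logger.warning(
            "samples with empty associated-gene sets (score 0 against all): %s",
            list(assoc.columns[empty]),
        )

    n_genes = A.shape[0]
    overlap = A.T.astype(np.int64) @ A.astype(np.int64)
    iu = np.triu_indices(len(sizes))
    k1 = sizes[iu[0]]
    k2 = sizes[iu[1]]
    m = overlap[iu]
    # upper-tail P(X >= m) for overlap of a k1-set and k2-set in n_genes genes
    p = stats.hypergeom.sf(m - 1, n_genes, k1, k2)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_fdr(p)
    with np.errstate(divide="ignore"):
        sc = np.minimum(-np.log10(adj), TROM_SCORE_CAP)
    S = np.zeros_like(overlap, dtype=float)
    S[iu] = sc
    S = S + S.T - np.diag(np.diag(S))
    ids = assoc.columns
    return TromMatrix(
        scores=pd.DataFrame(S, index=ids, columns=ids),
        z_threshold=z_threshold,
        set_sizes=pd.Series(sizes, index=ids),
    )


@dataclass
class PermutationResult:
    observed: float
    pvalue: float
    n_perm: int
    seed: int | None
    null_mean: float
    null_sd: float


def paired_trom_null(
    trom: TromMatrix,
    cohort: CohortTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of whether true pairs score higher than random pairs.

    The observed statistic is the median TROM score over the cohort's true
    primary–recurrent pairs.  Each null replicate randomly re-pairs the
    cohort's samples (two distinct samples per pair, drawn without
    replacement within a replicate) and takes the same median.  One-sided
    add-one p-value for a large observed median.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        logger.warning("n_perm = %d is small; p-value resolution is coarse", n_perm)
    ids = list(trom.sample_ids)
    pos = {s: i for i, s in enumerate(ids)}
    missing = [s for s in cohort.all_sample_ids() if s not in pos]
    if missing:
        raise ValueError(f"TROM matrix lacks cohort samples: {missing[:5]}")
    S = trom.scores.to_numpy()
    ip = np.array([pos[s] for s in cohort.primary_ids])
    ir = np.array([pos[s] for s in cohort.recurrent_ids])
    observed = float(np.median(S[ip, ir]))

    idx = np.concatenate([ip, ir])
    n_pairs = len(ip)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        null[b] = np.median(S[perm[:n_pairs], perm[n_pairs : 2 * n_pairs]])
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed,
        pvalue=p,
        n_perm=n_perm,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
    )


def sample_pc1(expr: ExpressionMatrix) -> pd.Series:
    """Score of each sample on the first principal component.

    Genes are centered across samples; the PC1 sign is fixed so that the gene
    with the largest absolute loading has a positive loading.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("degenerate expression matrix: zero variance everywhere")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loading = Vt[0]
    scores = U[:, 0] * s[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.sample_ids, name="pc1")


@dataclass
class LinearFit:
    """OLS fit of recurrent (y) on primary (x) summaries."""

    beta0: float
    beta1: float
    x_label: str = "primary"
    y_label: str = "recurrent"
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def fitted(self) -> np.ndarray:
        return self.beta0 + self.beta1 * self.x

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    def predict(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)


@dataclass
class GroupFitStat:
    ttr_group: str
    n: int
    rmse: float
    pvalue: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def fit_pr_line(x, y, x_label: str = "primary", y_label: str = "recurrent") -> LinearFit:
    """Ordinary least squares of y on x with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    beta1, beta0 = np.polyfit(x, y, 1)
    return LinearFit(beta0=float(beta0), beta1=float(beta1), x_label=x_label,
                     y_label=y_label, x=x, y=y)


def group_rmse(fit: LinearFit, x_sub, y_sub) -> float:
    """RMSE of a pair subset about the *global* fitted line:
    sqrt(mean (y_i - (beta0 + beta1 x_i))^2)."""
    x_sub = np.asarray(x_sub, dtype=float)
    y_sub = np.asarray(y_sub, dtype=float)
    if x_sub.size == 0:
        raise ValueError("empty subset")
    r = y_sub - fit.predict(x_sub)
    return float(np.sqrt(np.mean(r**2)))


def group_rmse_null(
    fit: LinearFit,
    group: str,
    n_in_group: int,
    observed: float,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> GroupFitStat:
    """Permutation null for a group's RMSE about the global line.

    Null replicates draw ``n_in_group`` pairs at random (without replacement)
    from the full fitted cohort and compute their RMSE about the same line;
    the one-sided add-one p-value asks whether the observed RMSE is small.
    """
    n_total = fit.x.size
    if n_in_group > n_total:
        raise ValueError("group larger than fitted cohort")
    if n_in_group < 3:
        raise ValueError("group too small for a meaningful RMSE")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    resid2 = fit.residuals**2
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pick = rng.choice(n_total, n_in_group, replace=False)
        null[b] = np.sqrt(resid2[pick].mean())
    p = (1.0 + float(np.sum(null <= observed))) / (n_perm + 1.0)
    return GroupFitStat(ttr_group=group, n=n_in_group, rmse=observed, pvalue=p,
                        n_perm=n_perm, seed=seed)


def _paired_fit_with_groups(
    x: np.ndarray,
    y: np.ndarray,
    cohort: CohortTable,
    n_perm: int,
    seed: int | None,
    x_label: str,
    y_label: str,
) -> tuple[LinearFit, list[GroupFitStat]]:
    fit = fit_pr_line(x, y, x_label=x_label, y_label=y_label)
    groups = cohort.table["ttr_group"].to_numpy()
    ss = np.random.SeedSequence(seed).spawn(len(TTR_GROUPS)) if seed is not None else [None] * 3
    out = []
    for gname, child in zip(TTR_GROUPS, ss):
        mask = groups == gname
        if mask.sum() < 3:
            logger.warning("TTR group %s has %d pairs; skipping RMSE null", gname, mask.sum())
            out.append(GroupFitStat(ttr_group=gname, n=int(mask.sum()),
                                    rmse=float("nan")))
            continue
        obs = group_rmse(fit, x[mask], y[mask])
        gseed = int(child.generate_state(1)[0] % (2**31)) if child is not None else None
        out.append(group_rmse_null(fit, gname, int(mask.sum()), obs, n_perm=n_perm, seed=gseed))
    return fit, out


def expression_pc1_fit(
    expr: ExpressionMatrix,
    cohort: CohortTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[LinearFit, list[GroupFitStat], pd.Series]:
    """PC1-summary regression of recurrent on primary with per-group RMSE nulls.

    Returns the fit, the per-TTR-group statistics, and the per-sample PC1
    scores (computed over the combined primary + recurrent matrix).
    """
    cohort.validate_against(expr)
    pc1 = sample_pc1(expr)
    x = pc1.loc[list(cohort.primary_ids)].to_numpy()
    y = pc1.loc[list(cohort.recurrent_ids)].to_numpy()
    fit, stats_ = _paired_fit_with_groups(
        x, y, cohort, n_perm, seed, x_label="primary PC1", y_label="recurrent PC1"
    )
    return fit, stats_, pc1


def tmb_pr_fit(
    tmb: TmbTable,
    cohort: CohortTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[LinearFit, list[GroupFitStat]]:
    """Recurrent-on-primary TMB regression with per-group RMSE nulls."""
    x = tmb.lookup(cohort.primary_ids).to_numpy()
    y = tmb.lookup(cohort.recurrent_ids).to_numpy()
    return _paired_fit_with_groups(
        x, y, cohort, n_perm, seed, x_label="primary TMB", y_label="recurrent TMB"
    )


def pearson_pr_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of paired primary/recurrent summaries."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
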