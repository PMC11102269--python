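"""Primary–recurrent divergence statistics.

Quantifies how far a recurrent tumor has moved from its matched primary:
per-pair expression RMSE, differential expression within TTR strata, paired
TMB contrasts, primary/recurrent mutation-class ratios, and the
hypermutation flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import bh_fdr
from .io import CohortTable, ExpressionMatrix, TmbTable, VariantTable

#: minimum alt-allele read support; calls with <= ALT_READ_MIN reads are dropped.
ALT_READ_MIN = 2


def pair_expression_rmse(expr: ExpressionMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Per-pair RMSE between recurrent and primary expression across genes.

    Returns a frame with pair_id, rmse_expr and ttr_group.  Both pair members
    must be present in the expression matrix.
    """
    cohort.validate_against(expr)
    P = expr.values[list(cohort.primary_ids)].to_numpy(dtype=float)
    R = expr.values[list(cohort.recurrent_ids)].to_numpy(dtype=float)
    rmse = np.sqrt(((R - P) ** 2).mean(axis=0))
    return pd.DataFrame(
        {
            "pair_id": cohort.pair_ids.to_numpy(),
            "rmse_expr": rmse,
            "ttr_group": cohort.table["ttr_group"].to_numpy(),
        }
    )


def paired_de(expr: ExpressionMatrix, cohort: CohortTable, group: str = "all") -> pd.DataFrame:
    """Differential expression between paired members within a TTR stratum.

    Fits, per gene, the linear model residual-expression ~ progression status
    restricted to the stratum's samples; ``log2fc`` is the recurrent-minus-
    primary mean difference (expression is already on the log scale), the
    p-value is the slope t-test, and FDR is BH across genes.
    """
    sub = cohort.group(group)
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has {len(sub)} pairs; need at least 3")
    sub.validate_against(expr)
    P = expr.values[list(sub.primary_ids)].to_numpy(dtype=float)
    R = expr.values[list(sub.recurrent_ids)].to_numpy(dtype=float)
    n = P.shape[1]
    log2fc = R.mean(axis=1) - P.mean(axis=1)
    # OLS on a binary regressor == equal-variance two-sample t-test
    var_pooled = (P.var(axis=1, ddof=1) + R.var(axis=1, ddof=1)) / 2.0
    se = np.sqrt(var_pooled * 2.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=2 * n - 2)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "fdr": np.maximum(fdr, p),
            "ttr_group": group,
        }
    ).reset_index(drop=True)


@dataclass
class TmbContrast:
    statistic: float
    pvalue: float
    n_pairs: int
    group: str
    median_primary: float
    median_recurrent: float


def tmb_contrast(tmb: TmbTable, cohort: CohortTable, group: str = "all") -> TmbContrast:
    """Two-sided Wilcoxon signed-rank test of paired recurrent vs primary TMB.

    Zeros are handled by the Pratt method.  All-zero differences are an error
    (the test statistic is undefined).
    """
    sub = cohort.group(group)
    tp = tmb.lookup(sub.primary_ids).to_numpy()
    tr = tmb.lookup(sub.recurrent_ids).to_numpy()
    diff = tr - tp
    if np.all(diff == 0):
        # identical vectors carry no evidence either way; report no rejection
        logging.getLogger(__name__).warning(
            "all paired TMB differences are zero in group %r; reporting p = 1", group
        )
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(tr, tp, zero_method="pratt", alternative="two-sided")
    return TmbContrast(
        statistic=float(stat),
        pvalue=float(p),
        n_pairs=len(sub),
        group=group,
        median_primary=float(np.median(tp)),
        median_recurrent=float(np.median(tr)),
    )


@dataclass
class MutationRatio:
    variant_class: str
    group: str
    count_primary: int
    count_recurrent: int
    ratio: float
    z: float
    pvalue: float


def one_proportion_z(a: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """One-proportion Z test of ``a`` successes in ``n`` trials against ``p0``."""
    if n <= 0:
        raise ValueError("one_proportion_z: n must be positive")
    phat = a / n
    z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def mutation_class_ratio(
    variants: VariantTable,
    cohort: CohortTable,
    group: str = "all",
    variant_class: str = "all",
) -> MutationRatio:
    """Primary/recurrent mutation-count ratio with a one-proportion Z test.

    Variant calls with alt-read support <= 2 are dropped first.  With
    ``a`` primary and ``b`` recurrent counts the test statistic is
    ``z = (a/(a+b) - 0.5) / sqrt(0.25/(a+b))``, two-sided normal p.
    """
    sub = cohort.group(group)
    t = variants.table
    t = t[t["alt_read_count"] > ALT_READ_MIN]
    if variant_class != "all":
        t = t[t["variant_class"] == variant_class]
    a = int(t["sample_id"].isin(set(sub.primary_ids)).sum())
    b = int(t["sample_id"].isin(set(sub.recurrent_ids)).sum())
    n = a + b
    if n == 0:
        raise ValueError(
            f"no qualifying variant calls for class {variant_class!r} in group {group!r}"
        )
    z, p = one_proportion_z(a, n)
    return MutationRatio(
        variant_class=variant_class,
        group=group,
        count_primary=a,
        count_recurrent=b,
        ratio=a / b if b else np.inf,
        z=z,
        pvalue=p,
    )


def hypermutation_flag(coding_gained: int, recurrent_burden: float) -> bool:
    """Hypermutation at recurrence: >=10 coding mutations gained and a
    recurrent burden strictly above 10 coding mutations per targeted Mb."""
    if coding_gained < 0 or recurrent_burden < 0:
        raise ValueError("counts and burdens must be non-negative")
    return coding_gained >= 10 and recurrent_burden > 10
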