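"""Relapse-time-associated gene selection, consensus subgrouping, and bulk
transcriptional subtype calling.

The selection cascade keeps protein-coding genes that (1) are *stable*
between paired primary and recurrent tumors in fast-relapsing patients
(TTR <= 6 months; DE p > 0.05), (2) are correlated between pair members
(Pearson p < 0.05), (3) carry prognostic signal in the primary tumor (both
Kaplan-Meier log-rank and univariate Cox p < 0.05), and (4) are expressed in
both the training and an external testing set.  Two alternative first
criteria ("deg" and "pfi_corr") reproduce simpler selection strategies used
as comparators.

Consensus clustering follows the Monti resampling scheme: repeated sample
subsampling, a base k-means clustering per replicate, and a consensus
co-clustering frequency matrix cut by hierarchical clustering.

Subtype calling scores each sample against named gene sets with a
single-sample, rank-based weighted running-sum enrichment statistic
(max-deviation ES, weight 0.75) and an empirical gene-permutation p-value;
a sample is assigned the subtype with the lowest p-value, ties broken by the
higher enrichment score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .divergence import one_proportion_z, paired_de
from .io import CohortTable, ExpressionMatrix, TTR_GROUPS
from .prognosis import cox_univariate

logger = logging.getLogger(__name__)

SELECTION_VARIANTS = ("ours", "deg", "pfi_corr")


# ---------------------------------------------------------------------------
# criterion primitives


def gene_pr_correlation(expr: ExpressionMatrix, cohort: CohortTable, gene: str) -> tuple[float, float]:
    """Pearson correlation of one gene's primary vs recurrent values across pairs."""
    x = expr.values.loc[gene, list(cohort.primary_ids)].to_numpy(dtype=float)
    y = expr.values.loc[gene, list(cohort.recurrent_ids)].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance for gene {gene!r}")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pairwise_pearson(P: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p between two gene × pair matrices."""
    n = P.shape[1]
    Pc = P - P.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    denom = np.sqrt((Pc**2).sum(axis=1) * (Rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Pc * Rc).sum(axis=1) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def km_logrank_median_split(x, time, event) -> float:
    """Log-rank p-value between above-median and at/below-median groups."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.size < 4:
        raise ValueError("too few samples for a median split")
    high = x > np.median(x)
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("median split produced an empty group")
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return float(res.p_value)


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class GeneSelectionReport:
    """Per-gene criterion flags and the cascade's survivors."""

    flags: pd.DataFrame  # boolean columns criterion1..criterion4
    selected: list[str]
    survivor_counts: dict[str, int]
    variant: str


def select_ttr_genes(
    expr: ExpressionMatrix,
    cohort: CohortTable,
    coding_genes: set[str],
    testing_expr: ExpressionMatrix | None = None,
    variant: str = "ours",
    expr_paired: ExpressionMatrix | None = None,
    alpha_de: float = 0.05,
    alpha_corr: float = 0.05,
    alpha_surv: float = 0.05,
    pfi_corr_r: float = 0.2,
    pfi_corr_p: float = 0.01,
) -> GeneSelectionReport:
    """Apply the four-criterion relapse-gene cascade.

    ``expr`` is the patient-level adjusted expression (covariates regressed
    out *without* the pair block): pair-member correlation (criterion 2) and
    primary-tumor survival association (criterion 3) are computed on it.
    The paired differential-expression criterion uses ``expr_paired``, the
    pair-adjusted residual matrix, when supplied (recommended; defaults to
    ``expr``, i.e. an unpaired contrast).  Regressing out pair identity makes
    pair members exact mirror images, so criteria 2–3 must never see a
    pair-adjusted matrix.

    ``variant='ours'`` is the stability-based cascade described above;
    ``'deg'`` replaces criteria 1–2 with "is a DEG between paired tumors at
    FDR < 0.05 over all pairs"; ``'pfi_corr'`` replaces them with "primary
    expression correlates with PFI (|r| >= 0.2, p < 0.01)".  Criteria 3 and 4
    are shared by all variants.  Survival fits use PFI with the relapse
    indicator as the event.
    """
    if variant not in SELECTION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {SELECTION_VARIANTS}")
    if not coding_genes:
        raise ValueError("empty protein-coding gene set")
    if expr_paired is None:
        expr_paired = expr
    if list(expr_paired.gene_ids) != list(expr.gene_ids):
        raise ValueError("expr and expr_paired must cover the same genes in the same order")
    genes = list(expr.gene_ids)
    P = expr.values[list(cohort.primary_ids)].to_numpy(dtype=float)
    time = cohort.table["pfi"].to_numpy(dtype=float)
    event = cohort.table["event"].to_numpy(dtype=int)

    flags = pd.DataFrame(index=pd.Index(genes, name="gene"))
    counts: dict[str, int] = {"input": len(genes)}

    if variant == "ours":
        de6 = paired_de(expr_paired, cohort, "le6").set_index("gene")
        flags["criterion1"] = (de6["p"] > alpha_de).reindex(genes).fillna(False)
        R = expr.values[list(cohort.recurrent_ids)].to_numpy(dtype=float)
        _, p_corr = _pairwise_pearson(P, R)
        flags["criterion2"] = p_corr < alpha_corr
    elif variant == "deg":
        de_all = paired_de(expr_paired, cohort, "all").set_index("gene")
        flags["criterion1"] = (de_all["fdr"] < alpha_de).reindex(genes).fillna(False)
        flags["criterion2"] = True
    else:  # pfi_corr
        pfi_row = np.broadcast_to(time, (len(genes), len(time)))
        r, p = _pairwise_pearson(P, np.array(pfi_row))
        flags["criterion1"] = (np.abs(r) >= pfi_corr_r) & (p < pfi_corr_p)
        flags["criterion2"] = True

    counts["after_criterion1"] = int(flags["criterion1"].sum())
    alive = flags["criterion1"] & flags["criterion2"]
    counts["after_criterion2"] = int(alive.sum())

    # criterion 3 evaluated only for survivors (two survival fits per gene)
    crit3 = pd.Series(False, index=flags.index)
    for gene in flags.index[alive]:
        x = expr.values.loc[gene, list(cohort.primary_ids)].to_numpy(dtype=float)
        try:
            p_km = km_logrank_median_split(x, time, event)
            p_cox = cox_univariate(x, time, event, name=gene).pvalue
        except Exception as exc:
            logger.warning("criterion 3 failed for %s: %s", gene, exc)
            continue
        crit3.loc[gene] = (p_km < alpha_surv) and (p_cox < alpha_surv)
    flags["criterion3"] = crit3
    alive = alive & crit3
    counts["after_criterion3"] = int(alive.sum())

    in_testing = (
        pd.Series(True, index=flags.index)
        if testing_expr is None
        else pd.Series(flags.index.isin(set(testing_expr.gene_ids)), index=flags.index)
    )
    flags["criterion4"] = pd.Series(flags.index.isin(coding_genes), index=flags.index) & in_testing
    alive = alive & flags["criterion4"]
    counts["selected"] = int(alive.sum())

    return GeneSelectionReport(
        flags=flags,
        selected=list(flags.index[alive]),
        survivor_counts=counts,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# consensus clustering (Monti resampling)


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame
    labels: pd.Series
    n_resamples: int
    subsample: float


def consensus_cluster(
    expr: ExpressionMatrix,
    k: int = 2,
    n_resamples: int = 1000,
    subsample: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Monti-style consensus clustering of samples on standardized expression.

    Each replicate subsamples ``subsample`` of the samples without
    replacement and clusters them with k-means on Euclidean distance; the
    consensus matrix is the co-clustering frequency among co-sampled
    replicates, and final labels come from average-linkage hierarchical
    clustering of ``1 - consensus``.
    """
    n = expr.shape[1]
    if k < 2 or k * 3 > n:
        raise ValueError(f"need at least 3*k samples for k={k} (have {n})")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    m = max(int(np.ceil(subsample * n)), k)
    for _ in range(n_resamples):
        pick = rng.choice(n, m, replace=False)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(X[pick])
        same = lab[:, None] == lab[None, :]
        together[np.ix_(pick, pick)] += same
        co_sampled[np.ix_(pick, pick)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, together / co_sampled, 0.0)
    np.fill_diagonal(consensus, 1.0)

    dist = squareform(1.0 - consensus, checks=False)
    labels = fcluster(linkage(dist, method="average"), k, criterion="maxclust")
    ids = expr.sample_ids
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=ids, columns=ids),
        labels=pd.Series(labels, index=ids, name="cluster"),
        n_resamples=n_resamples,
        subsample=subsample,
    )


# ---------------------------------------------------------------------------
# single-sample enrichment subtype calls


def _enrichment_scores(n_genes: int, hit_pos: np.ndarray, weight: float) -> np.ndarray:
    """Max-deviation running-sum ES for hit-position sets.

    ``hit_pos`` is (n_sets, set_size) of 0-based positions in a ranking of
    ``n_genes`` genes, position 0 = highest expressed.  Hits are weighted by
    descending rank weight ``(n_genes - position) ** weight``; misses
    decrement uniformly.  Rank-based, so any tie-free monotone transform of
    the expression values yields the same ES.
    """
    hp = np.sort(hit_pos, axis=1)
    s = hp.shape[1]
    w = (n_genes - hp).astype(float) ** weight
    cw = np.cumsum(w, axis=1)
    tot = cw[:, -1][:, None]
    miss_step = 1.0 / (n_genes - s)
    # running sum just after each hit, and just before each hit
    after = cw / tot - (hp + 1 - np.arange(1, s + 1)) * miss_step
    before = np.hstack([np.zeros((hp.shape[0], 1)), cw[:, :-1]]) / tot - (
        hp - np.arange(s)
    ) * miss_step
    dev = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


@dataclass
class SubtypeCall:
    sample_id: str
    subtype: str
    scores: dict[str, float]
    pvalues: dict[str, float]


def ssgsea_subtype(
    expr: ExpressionMatrix,
    signature_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 0.75,
    seed: int | None = None,
) -> list[SubtypeCall]:
    """Assign each sample the subtype whose gene set it is most enriched for.

    Per sample and set, the enrichment score is the max-deviation weighted
    running sum over the sample's expression ranking, with an empirical
    p-value from ``n_perm`` random same-size gene sets.  The subtype with the
    lowest p-value wins; among tied p-values the higher enrichment score
    wins (ties broken deterministically by set name order).
    """
    genes = list(expr.gene_ids)
    n_genes = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}
    set_names = list(signature_sets)
    set_pos: dict[str, np.ndarray] = {}
    for name in set_names:
        pos = np.array([pos_of[g] for g in signature_sets[name] if g in pos_of])
        if pos.size == 0:
            raise ValueError(f"signature set {name!r} shares no genes with the matrix")
        if pos.size < len(signature_sets[name]):
            logger.warning(
                "signature set %s: %d of %d genes absent from the matrix",
                name, len(signature_sets[name]) - pos.size, len(signature_sets[name]),
            )
        set_pos[name] = pos

    rng = np.random.default_rng(seed)
    # The gene-permutation null depends only on (n_genes, set size, weight),
    # so one null ES sample per distinct set size serves every sample.
    null_by_size: dict[int, np.ndarray] = {}
    for name in set_names:
        s = set_pos[name].size
        if s not in null_by_size:
            perm_pos = np.argsort(rng.random((n_perm, n_genes)), axis=1)[:, :s]
            null_by_size[s] = np.sort(_enrichment_scores(n_genes, perm_pos, weight))

    V = expr.values.to_numpy(dtype=float)
    calls = []
    for j, sid in enumerate(expr.sample_ids):
        ranking = np.argsort(-V[:, j], kind="mergesort")  # positions by descending expression
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[ranking] = np.arange(n_genes)
        scores, pvals = {}, {}
        for name in set_names:
            pos = rank_of[set_pos[name]]
            es = float(_enrichment_scores(n_genes, pos[None, :], weight)[0])
            es_null = null_by_size[pos.size]
            n_ge = es_null.size - np.searchsorted(es_null, es, side="left")
            pvals[name] = (1.0 + float(n_ge)) / (n_perm + 1.0)
            scores[name] = es
        best_p = min(pvals.values())
        tied = [nm for nm in set_names if pvals[nm] == best_p]
        subtype = max(tied, key=lambda nm: (scores[nm], -set_names.index(nm)))
        calls.append(SubtypeCall(sample_id=str(sid), subtype=subtype, scores=scores, pvalues=pvals))
    return calls


def load_gene_sets(path) -> dict[str, list[str]]:
    """Read named gene sets from a GMT-style TSV: name <tab> gene <tab> gene ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[1:] if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


# ---------------------------------------------------------------------------
# subtype transitions


@dataclass
class TransitionTable:
    counts: pd.DataFrame  # per group: to_mes, from_mes, stable, n
    direction_tests: pd.DataFrame  # per group: z, p comparing the two directions
    composition_tests: pd.DataFrame  # Fisher tests of mesenchymal share between groups


def transition_table(
    calls_primary: list[SubtypeCall],
    calls_recurrent: list[SubtypeCall],
    cohort: CohortTable,
) -> TransitionTable:
    """Mesenchymal-transition counts per TTR group with direction and
    composition tests.

    Per group, ``to_mes`` counts non-mesenchymal→mesenchymal pairs,
    ``from_mes`` the reverse, ``stable`` pairs keeping their subtype.  The
    one-proportion Z test compares the two transition directions; Fisher's
    exact tests compare each group's mesenchymal share (primary calls)
    against the rest of the cohort.
    """
    cp = {c.sample_id: c.subtype for c in calls_primary}
    cr = {c.sample_id: c.subtype for c in calls_recurrent}
    missing = [s for s in cohort.primary_ids if s not in cp] + [
        s for s in cohort.recurrent_ids if s not in cr
    ]
    if missing:
        raise ValueError(f"missing subtype calls for samples: {missing[:5]}")

    t = cohort.table
    rows, tests = [], []
    for gname in ("all",) + TTR_GROUPS:
        sub = t if gname == "all" else t[t["ttr_group"] == gname]
        prim = np.array([cp[s] for s in sub["sample_id_primary"]])
        rec = np.array([cr[s] for s in sub["sample_id_recurrent"]])
        to_mes = int(((prim != "mesenchymal") & (rec == "mesenchymal")).sum())
        from_mes = int(((prim == "mesenchymal") & (rec != "mesenchymal")).sum())
        stable = int((prim == rec).sum())
        rows.append(
            {"group": gname, "n": len(sub), "to_mes": to_mes, "from_mes": from_mes,
             "stable": stable}
        )
        if to_mes + from_mes > 0:
            z, p = one_proportion_z(to_mes, to_mes + from_mes)
        else:
            z, p = 0.0, 1.0
        tests.append({"group": gname, "z": z, "p": p})

    comp_rows = []
    prim_all = np.array([cp[s] for s in t["sample_id_primary"]])
    for gname in TTR_GROUPS:
        in_g = (t["ttr_group"] == gname).to_numpy()
        a = int((prim_all[in_g] == "mesenchymal").sum())
        b = int(in_g.sum()) - a
        c = int((prim_all[~in_g] == "mesenchymal").sum())
        d = int((~in_g).sum()) - c
        _, p = stats.fisher_exact([[a, b], [c, d]])
        comp_rows.append({"group": gname, "mes": a, "non_mes": b, "p_vs_rest": float(p)})

    return TransitionTable(
        counts=pd.DataFrame(rows),
        direction_tests=pd.DataFrame(tests),
        composition_tests=pd.DataFrame(comp_rows),
    )
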