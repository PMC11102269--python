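"""Progression-free-survival modeling: Cox fits, stepwise gene selection,
the exponentiated risk score, dichotomized Kaplan-Meier comparison, horizon
ROC, concordance, and nomogram export.

The risk score of a patient is ``exp(sum_i coefficient_i * expression_i)``
over the model's genes, with covariate-adjusted expression.  Patients are
dichotomized at a fixed cutoff (high iff score >= cutoff), which makes the
rule portable to external cohorts without refitting.

All Cox fits use lifelines' partial likelihood with Efron tie handling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Ordered gene list with Cox log-hazard coefficients and a score cutoff."""

    genes: list[str]
    coefficients: np.ndarray
    cutoff: float
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != self.coefficients.size:
            raise ValueError("genes and coefficients must have equal length")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def to_json(self, path) -> None:
        doc = {
            "genes": list(self.genes),
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
            "training_summary": self.training_summary,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            genes=doc["genes"],
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            cutoff=doc["cutoff"],
            training_summary=doc.get("training_summary", {}),
        )


def seven_gene_model() -> RiskModel:
    """The published seven-gene IDH-wt GBM progression risk model.

    Coefficients are per unit covariate-adjusted log2 expression; the score
    cutoff 1.04 is the training-cohort median risk score.  High expression of
    CDKL1 and CD101 is protective (negative coefficients); the other five
    genes are risk factors.
    """
    return RiskModel(
        genes=["SIGLEC14", "GHRHR", "TAS2R1", "CDKL1", "ZSCAN10", "TBX15", "CD101"],
        coefficients=np.array([0.3296, 0.2804, 2.1475, -0.7833, 0.8261, 0.5557, -0.4108]),
        cutoff=1.04,
    )


@dataclass
class SurvivalFit:
    """Per-variable Cox summary."""

    variable: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    n_events: int
    c_index: float
    warnings: list[str] = field(default_factory=list)


def _fit_cox(df: pd.DataFrame, duration_col: str = "time", event_col: str = "event"):
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    notes = [str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)]
    return cph, notes


def cox_univariate(x, time, event, name: str = "x") -> SurvivalFit:
    """Univariate Cox proportional-hazards fit (Efron ties).

    Warns below 10 events; monotone-likelihood / convergence problems are
    surfaced in the result's ``warnings`` or raised as ``ConvergenceError``.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    notes = []
    if n_events < 10:
        notes.append(f"only {n_events} events; estimates are unstable")
        logger.warning("cox_univariate(%s): %s", name, notes[-1])
    df = pd.DataFrame({name: x, "time": time, "event": event})
    try:
        cph, fit_notes = _fit_cox(df)
    except ConvergenceError as exc:
        raise ConvergenceError(f"Cox fit failed for {name!r}: {exc}") from exc
    notes.extend(fit_notes)
    s = cph.summary.loc[name]
    return SurvivalFit(
        variable=name,
        coef=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        pvalue=float(s["p"]),
        n=len(df),
        n_events=n_events,
        c_index=float(cph.concordance_index_),
        warnings=notes,
    )


def cox_multivariate(df: pd.DataFrame, covariates: list[str], time_col: str = "time",
                     event_col: str = "event") -> list[SurvivalFit]:
    """Multi-covariate Cox fit; one SurvivalFit per covariate."""
    sub = df[covariates + [time_col, event_col]].dropna()
    cph, notes = _fit_cox(sub, duration_col=time_col, event_col=event_col)
    out = []
    for cov in cph.summary.index:
        s = cph.summary.loc[cov]
        out.append(
            SurvivalFit(
                variable=str(cov),
                coef=float(s["coef"]),
                hr=float(s["exp(coef)"]),
                ci_low=float(np.exp(s["coef lower 95%"])),
                ci_high=float(np.exp(s["coef upper 95%"])),
                pvalue=float(s["p"]),
                n=len(sub),
                n_events=int(sub[event_col].sum()),
                c_index=float(cph.concordance_index_),
                warnings=notes,
            )
        )
    return out


def stepwise_cox(
    candidates: pd.DataFrame,
    time,
    event,
    sle: float = 0.05,
    sls: float = 0.05,
    max_steps: int = 100,
) -> RiskModel:
    """Bidirectional stepwise Cox selection over candidate genes.

    At each step the candidate whose addition gives the smallest
    likelihood-ratio p-value enters if p < ``sle`` (ties broken by candidate
    order); then any included variable whose Wald p exceeds ``sls`` is
    removed (largest first).  Iterates to a fixed point, guarded by a step
    cap; deterministic given the candidate column order.  The returned model
    carries the final coefficients and a cutoff equal to the median training
    risk score.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidate variables supplied")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    base = pd.DataFrame({"time": time, "event": event}, index=candidates.index)

    def _ll(cols: list[str]) -> tuple[float, CoxPHFitter | None]:
        if not cols:
            return _null_log_likelihood(time, event), None
        cph, _ = _fit_cox(pd.concat([candidates[cols], base], axis=1))
        return float(cph.log_likelihood_), cph

    included: list[str] = []
    ll_cur, fit_cur = _ll(included)
    seen = set()
    for _ in range(max_steps):
        changed = False
        # forward: best LR entry
        best_p, best_c, best_ll = None, None, None
        for c in candidates.columns:
            if c in included:
                continue
            try:
                ll_new, _ = _ll(included + [c])
            except ConvergenceError:
                continue
            lr = max(2.0 * (ll_new - ll_cur), 0.0)
            p = float(stats.chi2.sf(lr, 1))
            if best_p is None or p < best_p:
                best_p, best_c, best_ll = p, c, ll_new
        if best_p is not None and best_p < sle:
            included.append(best_c)
            ll_cur = best_ll
            changed = True
        # backward: Wald removal
        while included:
            ll_cur, fit_cur = _ll(included)
            pvals = fit_cur.summary.loc[included, "p"]
            worst = pvals.idxmax()
            if pvals.loc[worst] > sls:
                included.remove(worst)
                changed = True
            else:
                break
        state = tuple(sorted(included))
        if not changed:
            break
        if state in seen:
            logger.warning("stepwise_cox: selection cycled; stopping at %s", included)
            break
        seen.add(state)
    else:
        raise RuntimeError(f"stepwise_cox did not stabilize within {max_steps} steps")

    if included:
        ll_cur, fit_cur = _ll(included)
        coefs = fit_cur.params_.loc[included].to_numpy()
        cindex = float(fit_cur.concordance_index_)
    else:
        coefs = np.empty(0)
        cindex = 0.5
    scores = np.exp(candidates[included].to_numpy() @ coefs) if included else np.ones(len(base))
    return RiskModel(
        genes=list(included),
        coefficients=coefs,
        cutoff=float(np.median(scores)),
        training_summary={"c_index": cindex, "n": len(base), "n_events": int(event.sum())},
    )


def _null_log_likelihood(time: np.ndarray, event: np.ndarray) -> float:
    """Log partial likelihood of the empty Cox model.

    With all relative hazards equal to one, the Efron and Breslow tie
    corrections coincide: the j-th of d tied events at an event time with
    ``n_i`` subjects at risk contributes ``-log(n_i - j)``.
    """
    ll = 0.0
    for utime in np.unique(time[event == 1]):
        d = int(((time == utime) & (event == 1)).sum())
        at_risk = int((time >= utime).sum())
        for j in range(d):
            ll -= np.log(at_risk - j)
    return ll


def risk_score(expression: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Per-patient risk score ``exp(sum coefficient_i * expression_i)``.

    ``expression`` is samples × genes (or genes × samples, auto-oriented);
    all model genes must be present.
    """
    df = expression
    if not set(model.genes).issubset(df.columns):
        if set(model.genes).issubset(df.index):
            df = df.T
        else:
            missing = [g for g in model.genes if g not in df.columns and g not in df.index]
            raise KeyError(f"expression table lacks model genes: {missing}")
    lp = df[model.genes].to_numpy(dtype=float) @ model.coefficients
    return pd.Series(np.exp(lp), index=df.index, name="risk_score")


def dichotomize(scores: pd.Series, cutoff: float | None = None) -> pd.Series:
    """Label scores ``high`` iff score >= cutoff (default: median of scores)."""
    s = pd.Series(scores)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite risk scores")
    if cutoff is None:
        cutoff = float(s.median())
    return pd.Series(np.where(s >= cutoff, "high", "low"), index=s.index, name="risk_group")


@dataclass
class KmResult:
    pvalue: float
    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]


def km_logrank(groups, time, event) -> KmResult:
    """Kaplan-Meier curves per group with a log-rank test.

    Two groups use the standard log-rank test; more use its multivariate
    extension.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    curves, medians = {}, {}
    for lab in labels:
        m = (groups == lab).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
        medians[str(lab)] = float(kmf.median_survival_time_)
    if len(labels) == 2:
        m = (groups == labels[0]).to_numpy()
        res = logrank_test(time[m], time[~m], event[m], event[~m])
    else:
        res = multivariate_logrank_test(time, groups, event)
    return KmResult(pvalue=float(res.p_value), curves=curves, medians=medians)


def roc_at_horizon(scores, time, event, horizon: float, ipcw: bool = False) -> float:
    """AUC for relapse-by-horizon classification.

    The binary label is relapse observed by ``horizon`` months; patients
    censored before the horizon without an event are excluded (plain binary
    ROC).  With ``ipcw=True`` an inverse-probability-of-censoring-weighted
    (Uno-type) AUC is computed instead, keeping all subjects.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if ipcw:
        return _ipcw_auc(scores, time, event, horizon)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    usable = case | control
    labels = case[usable].astype(int)
    if labels.min() == labels.max():
        raise ValueError("only one class at this horizon; AUC undefined")
    return float(roc_auc_score(labels, scores[usable]))


def _ipcw_auc(scores, time, event, horizon) -> float:
    # censoring survival G(t) via KM of the censoring distribution
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    G = lambda t: float(np.clip(kmf.survival_function_at_times(t).iloc[0], 1e-8, 1.0))
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("only one class at this horizon; AUC undefined")
    w_case = np.array([1.0 / G(t) for t in time[case]])
    w_ctrl = np.full(int(control.sum()), 1.0 / G(horizon))
    sc, sk = scores[case], scores[control]
    gt = (sc[:, None] > sk[None, :]).astype(float) + 0.5 * (sc[:, None] == sk[None, :])
    W = w_case[:, None] * w_ctrl[None, :]
    return float((gt * W).sum() / W.sum())


def c_index(scores, time, event) -> float:
    """Harrell's concordance of risk scores with observed event ordering."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events")
    # higher score = higher risk = shorter time, so concordance uses -score
    return float(concordance_index(time, -scores, event))


def nomogram_export(
    model: RiskModel,
    expression: pd.DataFrame,
    time,
    event,
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0),
    grid: int = 11,
) -> dict[str, pd.DataFrame]:
    """Nomogram tables: per-gene point axes and total-points → PFS mapping.

    Each gene's contribution ``coef * x`` over its observed range is rescaled
    so the largest span equals 100 points.  Total points map to 1/2/3-year
    progression-free probabilities through the Breslow baseline survival of
    the model evaluated on the supplied training data.
    """
    df = expression
    if not set(model.genes).issubset(df.columns):
        df = df.T
    df = df[model.genes]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lo = df.min(axis=0).to_numpy()
    hi = df.max(axis=0).to_numpy()
    if np.any(hi - lo == 0):
        zero = [g for g, l, h in zip(model.genes, lo, hi) if h == l]
        raise ValueError(f"zero observed range for genes {zero}; nomogram axis undefined")
    span = np.abs(model.coefficients) * (hi - lo)
    max_span = span.max()
    if max_span == 0:
        raise ValueError("all coefficients are zero; nomogram undefined")

    rows = []
    for g, c, l, h in zip(model.genes, model.coefficients, lo, hi):
        xs = np.linspace(l, h, grid)
        # points grow with the risk contribution c*x, anchored at the
        # least-risk end of the observed range
        contrib = c * xs
        pts = (contrib - contrib.min()) / max_span * 100.0
        for x, p in zip(xs, pts):
            rows.append({"gene": g, "expression": x, "points": p})
    axes = pd.DataFrame(rows)

    # Breslow baseline cumulative hazard with linear predictors centered
    lp = df.to_numpy(dtype=float) @ model.coefficients
    lp_mean = lp.mean()
    rel = np.exp(lp - lp_mean)
    order = np.argsort(time, kind="mergesort")
    H0 = {}
    for h in horizons:
        mask = (time[order] <= h) & (event[order] == 1)
        h0 = 0.0
        for ti in time[order][mask]:
            at_risk = rel[time >= ti].sum()
            h0 += 1.0 / at_risk
        H0[h] = h0

    total_min = sum(
        min(c * l, c * h) for c, l, h in zip(model.coefficients, lo, hi)
    )
    pts_grid = np.linspace(0, 100.0 * span.sum() / max_span, 25)
    rows = []
    for tp in pts_grid:
        lp_val = total_min + tp / 100.0 * max_span
        row = {"total_points": tp}
        for h in horizons:
            row[f"pfs_{int(h)}m"] = float(np.exp(-H0[h] * np.exp(lp_val - lp_mean)))
        rows.append(row)
    mapping = pd.DataFrame(rows)
    return {"axes": axes, "survival_mapping": mapping}
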