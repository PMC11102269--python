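"""Synthetic paired primary–recurrent cohort generator.

The generator emulates the statistical structure the longitudinal analysis
assumes, so every downstream stage has a ground-truth test bed:

* paired samples sharing a per-pair, per-gene latent baseline;
* additive covariate effects on log2 expression (age, gender, data source);
* a random-walk transcriptomic drift between primary and recurrence whose
  variance grows linearly with the time to relapse (TTR);
* relapse times drawn from an exponential proportional-hazards model on a
  planted gene signature measured in the primary tumor, with independent
  exponential right-censoring;
* tumor mutation burden that accumulates with TTR in the recurrent sample;
* per-sample mutation-class count vectors scaled by burden.

Expression is generated on the log2 scale and exported as TPM via
``2**x - 1`` floored at zero, matching what the preprocessing stage expects
to ingest.  A single integer seed controls all randomness through named
sub-streams, so identical configurations yield bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CohortTable,
    ExpressionMatrix,
    TmbTable,
    VariantTable,
    VARIANT_CLASSES,
    write_cohort,
    write_expression,
    write_tmb,
    write_variants,
)

_DATA_SOURCES = ("siteA", "siteB", "siteC")
_SOURCE_PROBS = (0.5, 0.3, 0.2)

# Baseline per-class mutation rates per sample at a burden of 2 mutations/Mb.
_CLASS_RATES = {
    "missense": 20.0,
    "silent": 8.0,
    "other": 3.0,
    "nonsense": 2.0,
    "frameshift_del": 1.5,
    "splice_site": 1.5,
    "frameshift_ins": 1.0,
}


def _default_covariate_effects() -> dict[str, float]:
    # Per-gene effect-size standard deviations on the log2 scale.  "pair" is
    # the shared per-pair baseline that makes true pairs more alike than
    # random sample pairs; it dominates, as batch/pair effects do in paired
    # bulk RNA-seq.
    return {"age": 0.1, "gender": 0.3, "data_source": 0.4, "pair": 1.0}


def _default_signature_beta() -> np.ndarray:
    # Alternating-sign log-hazard effects per standardized expression unit.
    return np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5])


@dataclass
class SimulationConfig:
    """Parameters of the paired-cohort generator.

    Defaults describe an 87-pair IDH-wt-like cohort with a clearly detectable
    drift and hazard signal; they are illustrative magnitudes (the structure,
    not the effect sizes, is what real cohorts pin down).
    """

    n_pairs: int = 87
    n_genes: int = 2000
    n_signature_genes: int = 8
    n_drift_genes: int = 600
    sigma_noise: float = 0.5
    #: drift standard deviation per sqrt(month): Var(delta) = sigma^2 * TTR.
    sigma_drift_per_month: float = 0.15
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    #: per-month exponential relapse rate at the signature baseline; 0.07
    #: puts the median time to relapse near 10 months, the regime reported
    #: for paired IDH-wt GBM cohorts.
    baseline_hazard: float = 0.07
    signature_beta: np.ndarray = field(default_factory=_default_signature_beta)
    #: per-month independent exponential censoring rate.
    censor_rate: float = 0.01
    #: mutations/Mb gained per month of TTR in the recurrent sample.
    tmb_slope: float = 0.08
    #: number of latent co-expression programs (sample-level composition
    #: variation); genes load on shared programs, giving the gene-gene
    #: correlation bulk transcriptomes exhibit.
    n_programs: int = 10
    #: per-gene expression sd contributed by the programs.
    sigma_program: float = 0.8
    #: correlation of program activities within a pair at TTR -> 0 (two
    #: biopsies of the same tumor share composition); 0 makes activities
    #: fully independent.
    pair_program_rho: float = 0.7
    #: exponential decay rate of that correlation per month of TTR, so
    #: composition — like per-gene expression — drifts with elapsed time.
    program_decay_per_month: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        self.signature_beta = np.atleast_1d(np.asarray(self.signature_beta, dtype=float))
        if self.signature_beta.size == 1 and self.n_signature_genes > 1:
            self.signature_beta = np.repeat(self.signature_beta, self.n_signature_genes)
        for name in ("n_pairs", "n_genes", "n_signature_genes", "n_drift_genes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                if name == "n_drift_genes" and v == 0:
                    continue
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_signature_genes + self.n_drift_genes > self.n_genes:
            raise ValueError("n_signature_genes + n_drift_genes exceeds n_genes")
        rates = {
            "sigma_noise": self.sigma_noise,
            "sigma_drift_per_month": self.sigma_drift_per_month,
            "baseline_hazard": self.baseline_hazard,
            "censor_rate": self.censor_rate,
            "tmb_slope": self.tmb_slope,
        }
        for name, v in rates.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.n_programs < 0 or not np.isfinite(self.sigma_program) or self.sigma_program < 0:
            raise ValueError("n_programs must be >= 0 and sigma_program finite and >= 0")
        if not (0.0 <= self.pair_program_rho <= 1.0):
            raise ValueError("pair_program_rho must lie in [0, 1]")
        if not np.isfinite(self.program_decay_per_month) or self.program_decay_per_month < 0:
            raise ValueError("program_decay_per_month must be finite and >= 0")
        if not np.all(np.isfinite(self.signature_beta)):
            raise ValueError("signature_beta contains non-finite entries")
        if self.signature_beta.size != self.n_signature_genes:
            raise ValueError(
                f"signature_beta length {self.signature_beta.size} != "
                f"n_signature_genes {self.n_signature_genes}"
            )
        for k, v in self.covariate_effects.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"covariate effect sd for {k!r} must be >= 0, got {v!r}")


@dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort."""

    signature_genes: list[str]
    drift_genes: list[str]
    signature_beta: np.ndarray
    linear_predictor: np.ndarray
    #: per-pair drift standard deviation, sigma_drift_per_month * sqrt(TTR).
    drift_sd: np.ndarray


@dataclass
class SyntheticCohort:
    tpm_primary: ExpressionMatrix
    tpm_recurrent: ExpressionMatrix
    cohort: CohortTable
    variants: VariantTable
    tmb: TmbTable
    truth: CohortTruth

    def write(self, outdir) -> dict[str, str]:
        """Write all tables as TSV into ``outdir``; returns the path map."""
        from pathlib import Path

        outdir = Path(outdir)
        paths = {
            "expression_primary": outdir / "expression_primary.tsv",
            "expression_recurrent": outdir / "expression_recurrent.tsv",
            "clinical": outdir / "clinical.tsv",
            "variants": outdir / "variants.tsv",
            "tmb": outdir / "tmb.tsv",
        }
        write_expression(self.tpm_primary, paths["expression_primary"])
        write_expression(self.tpm_recurrent, paths["expression_recurrent"])
        write_cohort(self.cohort, paths["clinical"])
        write_variants(self.variants, paths["variants"])
        write_tmb(self.tmb, paths["tmb"])
        return {k: str(v) for k, v in paths.items()}


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one paired cohort under the configured generative model."""
    c = config
    rng = _streams(
        c.seed,
        ("genes", "clinical", "hazard", "noise", "drift", "tmb", "variants", "programs"),
    )
    n, g = c.n_pairs, c.n_genes

    gene_ids = np.array([f"G{i:05d}" for i in range(g)])
    signature_genes = list(gene_ids[: c.n_signature_genes])
    drift_genes = list(gene_ids[c.n_signature_genes : c.n_signature_genes + c.n_drift_genes])

    pair_ids = np.array([f"P{i:03d}" for i in range(n)])
    primary_ids = np.array([f"{p}_P" for p in pair_ids])
    recurrent_ids = np.array([f"{p}_R" for p in pair_ids])

    # --- clinical covariates -------------------------------------------------
    rc = rng["clinical"]
    age = np.clip(rc.normal(60.0, 10.0, n), 18.0, 90.0)
    gender = rc.choice(["female", "male"], n)
    source = rc.choice(_DATA_SOURCES, n, p=_SOURCE_PROBS)
    mgmt = rc.choice(["methylated", "unmethylated"], n)
    tmz = rc.choice([1, 0], n, p=[0.8, 0.2])
    resection = rc.choice(["total", "subtotal"], n)

    # --- latent expression ---------------------------------------------------
    rg = rng["genes"]
    mu = rg.uniform(1.0, 6.0, g)  # gene-level log2 baselines
    eff = c.covariate_effects
    a_g = rg.normal(0.0, eff.get("age", 0.0), g)
    g_g = rg.normal(0.0, eff.get("gender", 0.0), g)
    s_gl = rg.normal(0.0, eff.get("data_source", 0.0), (g, len(_DATA_SOURCES)))

    z_age = (age - 60.0) / 10.0
    male = (gender == "male").astype(float)
    src_idx = np.array([_DATA_SOURCES.index(s) for s in source])

    latent = (
        mu[:, None]
        + a_g[:, None] * z_age[None, :]
        + g_g[:, None] * male[None, :]
        + s_gl[:, src_idx]
    )
    pair_sd = eff.get("pair", 0.0)
    if pair_sd > 0:
        latent = latent + rng["genes"].normal(0.0, pair_sd, (g, n))

    # Sample-level co-expression programs: genes load on shared latent
    # factors whose activities are drawn independently per *sample* (not per
    # pair), emulating composition variation between any two biopsies.  This
    # is what gives the matrix realistic gene-gene correlation.
    have_programs = c.n_programs > 0 and c.sigma_program > 0
    if have_programs:
        rp = rng["programs"]
        loadings = rp.normal(0.0, 1.0, (g, c.n_programs))
        scale = c.sigma_program / np.sqrt(c.n_programs)
        act_p = rp.normal(0.0, 1.0, (c.n_programs, n))
        act_fresh = rp.normal(0.0, 1.0, (c.n_programs, n))
        prog_p = scale * loadings @ act_p
    else:
        prog_p = 0.0

    rn = rng["noise"]
    log_primary = latent + prog_p + rn.normal(0.0, c.sigma_noise, (g, n))

    # --- relapse times from a proportional-hazards model on the signature ----
    sig = log_primary[: c.n_signature_genes]
    sd = sig.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z_sig = (sig - sig.mean(axis=1, keepdims=True)) / sd[:, None]
    eta = c.signature_beta @ z_sig
    rh = rng["hazard"]
    ttr = rh.exponential(1.0, n) / (c.baseline_hazard * np.exp(eta))
    ttr = np.maximum(ttr, 1e-3)
    if c.censor_rate > 0:
        censor = rh.exponential(1.0 / c.censor_rate, n)
    else:
        censor = np.full(n, np.inf)
    pfi = np.minimum(ttr, censor)
    event = (ttr <= censor).astype(int)

    # --- drift and recurrent expression -------------------------------------
    # Program-activity correlation between the two biopsies decays with TTR:
    # composition, like per-gene expression, drifts during the elapsed time.
    if have_programs:
        rho = c.pair_program_rho * np.exp(-c.program_decay_per_month * ttr)
        act_r = rho[None, :] * act_p + np.sqrt(1.0 - rho[None, :] ** 2) * act_fresh
        prog_r = scale * loadings @ act_r
    else:
        prog_r = 0.0

    drift_sd = c.sigma_drift_per_month * np.sqrt(ttr)
    delta = np.zeros((g, n))
    if c.n_drift_genes > 0 and c.sigma_drift_per_month > 0:
        rows = slice(c.n_signature_genes, c.n_signature_genes + c.n_drift_genes)
        delta[rows] = rng["drift"].normal(0.0, 1.0, (c.n_drift_genes, n)) * drift_sd[None, :]
    log_recurrent = latent + prog_r + delta + rn.normal(0.0, c.sigma_noise, (g, n))

    tpm_p = np.maximum(np.exp2(log_primary) - 1.0, 0.0)
    tpm_r = np.maximum(np.exp2(log_recurrent) - 1.0, 0.0)

    # --- TMB and variants ----------------------------------------------------
    rt = rng["tmb"]
    tmb_p = rt.gamma(4.0, 0.5, n)
    tmb_r = np.maximum(tmb_p + c.tmb_slope * ttr + rt.normal(0.0, 0.3, n), 0.0)

    variants = _draw_variants(
        rng["variants"],
        sample_ids=np.concatenate([primary_ids, recurrent_ids]),
        burdens=np.concatenate([tmb_p, tmb_r]),
        gene_ids=gene_ids,
    )

    cohort = CohortTable(
        pd.DataFrame(
            {
                "pair_id": pair_ids,
                "patient_id": [f"PT{i:03d}" for i in range(n)],
                "sample_id_primary": primary_ids,
                "sample_id_recurrent": recurrent_ids,
                "age": np.round(age, 1),
                "gender": gender,
                "data_source": source,
                "ttr": ttr,
                "pfi": pfi,
                "event": event,
                "idh_status": "IDHwt",
                "mgmt_status": mgmt,
                "tmz_treated": tmz,
                "extent_of_resection": resection,
            }
        )
    )
    tmb = TmbTable(
        pd.DataFrame(
            {
                "sample_id": np.concatenate([primary_ids, recurrent_ids]),
                "tmb": np.concatenate([tmb_p, tmb_r]),
            }
        )
    )
    truth = CohortTruth(
        signature_genes=signature_genes,
        drift_genes=drift_genes,
        signature_beta=c.signature_beta.copy(),
        linear_predictor=eta,
        drift_sd=drift_sd,
    )
    return SyntheticCohort(
        tpm_primary=ExpressionMatrix(pd.DataFrame(tpm_p, index=gene_ids, columns=primary_ids)),
        tpm_recurrent=ExpressionMatrix(
            pd.DataFrame(tpm_r, index=gene_ids, columns=recurrent_ids)
        ),
        cohort=cohort,
        variants=variants,
        tmb=tmb,
        truth=truth,
    )


def _draw_variants(rng, sample_ids, burdens, gene_ids) -> VariantTable:
    rows = []
    for sid, burden in zip(sample_ids, burdens):
        scale = max(burden, 0.0) / 2.0
        for vclass in VARIANT_CLASSES:
            k = rng.poisson(_CLASS_RATES[vclass] * scale)
            if k == 0:
                continue
            genes = rng.choice(gene_ids, k)
            # ~10% of calls fall at or below the 2-read support threshold so
            # the downstream alt-read filter has something to remove.
            low = rng.random(k) < 0.1
            reads = np.where(low, 1 + rng.poisson(0.8, k), 3 + rng.poisson(10.0, k))
            reads = np.where(low, np.minimum(reads, 2), reads)
            for gene, r in zip(genes, reads):
                rows.append((sid, gene, vclass, int(r)))
    return VariantTable(
        pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class", "alt_read_count"])
    )


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Fully exchangeable cohort for permutation-test calibration.

    All drift, planted-signature and TMB-slope effects are zeroed, and so are
    the shared per-pair baseline and the covariate effects: every sample is an
    i.i.d. draw, so any re-pairing of the cohort has the same distribution as
    the labeled pairing.  Relapse times are exponential and independent of
    expression.  Planted-truth gene lists are empty.
    """
    from dataclasses import replace

    null_cfg = replace(
        config,
        sigma_drift_per_month=0.0,
        signature_beta=np.zeros(config.n_signature_genes),
        tmb_slope=0.0,
        covariate_effects={k: 0.0 for k in config.covariate_effects},
        pair_program_rho=0.0,
    )
    cohort = generate_cohort(null_cfg)
    cohort.truth = CohortTruth(
        signature_genes=[],
        drift_genes=[],
        signature_beta=np.zeros(0),
        linear_predictor=cohort.truth.linear_predictor,
        drift_sd=np.zeros(config.n_pairs),
    )
    return cohort


def synthetic_glass_like_clinical(seed: int = 0) -> CohortTable:
    """Synthetic stand-in for a paired-GBM consortium clinical table.

    The deposited table this emulates is access-restricted; this constructs a
    synthetic cohort table with the published marginal counts of the paired
    IDH-wt GBM study population: 98 GBM pairs of which 87 are IDH wild-type
    with complete age/gender/data-source/TTR information, TTR strata of
    23 (<=6 months), 33 (7-12 months) and 31 (>12 months) pairs, and 69
    TMZ-treated cases.  Individual ages, TTR values and sample identifiers
    are invented; only the marginals are meaningful.
    """
    rng = np.random.default_rng(seed)
    n_le6, n_mid, n_gt12, n_mut, n_na = 23, 33, 31, 8, 3
    ttr = np.concatenate(
        [
            rng.uniform(1.0, 6.0, n_le6),
            rng.uniform(6.0 + 1e-6, 12.0, n_mid),
            rng.uniform(12.0 + 1e-6, 60.0, n_gt12),
            rng.uniform(2.0, 40.0, n_mut + n_na),
        ]
    )
    n = n_le6 + n_mid + n_gt12 + n_mut + n_na
    idh = np.array(["IDHwt"] * 87 + ["IDHmut"] * n_mut + [np.nan] * n_na, dtype=object)
    tmz = np.zeros(n, dtype=int)
    tmz[rng.choice(87, 69, replace=False)] = 1
    pair_ids = [f"GP{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "patient_id": [f"GPT{i:03d}" for i in range(n)],
            "sample_id_primary": [f"{p}_P" for p in pair_ids],
            "sample_id_recurrent": [f"{p}_R" for p in pair_ids],
            "age": np.round(rng.normal(60, 10, n), 1),
            "gender": rng.choice(["female", "male"], n),
            "data_source": rng.choice(list(_DATA_SOURCES), n),
            "ttr": ttr,
            "pfi": ttr,
            "event": 1,
            "idh_status": idh,
            "mgmt_status": rng.choice(["methylated", "unmethylated"], n),
            "tmz_treated": tmz,
            "extent_of_resection": rng.choice(["total", "subtotal"], n),
        }
    )
    return CohortTable(table)
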