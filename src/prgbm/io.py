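"""Tabular I/O and validated containers for the paired-cohort pipeline.

All tables travel as TSV (tab-separated, UTF-8, '.' decimal, missing values
encoded as ``NA``).  Four container types cover the pipeline's inputs:

* :class:`ExpressionMatrix` — gene × sample values with a processing-stage tag,
* :class:`CohortTable` — one row per patient-matched primary–recurrent pair,
* :class:`VariantTable` — per-sample somatic variant calls (MAF-like),
* :class:`TmbTable` — per-sample tumor mutation burden (mutations/Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

STAGES = ("tpm", "log2p1", "residual")

#: Time-to-relapse strata: <=6 months, 7-12 months, >12 months.
TTR_GROUPS = ("le6", "m7_12", "gt12")

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_del",
    "frameshift_ins",
    "silent",
    "other",
)

COHORT_COLUMNS = [
    "pair_id",
    "patient_id",
    "sample_id_primary",
    "sample_id_recurrent",
    "age",
    "gender",
    "data_source",
    "ttr",
    "pfi",
    "event",
    "idh_status",
    "mgmt_status",
    "tmz_treated",
    "extent_of_resection",
]


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


def ttr_group_of(ttr: float) -> str | float:
    """Assign the TTR stratum for a relapse time in months.

    ``<= 6`` -> ``le6``; ``> 6 and <= 12`` -> ``m7_12``; ``> 12`` -> ``gt12``.
    Missing TTR yields NaN.
    """
    if ttr is None or (isinstance(ttr, float) and np.isnan(ttr)):
        return np.nan
    if ttr <= 6:
        return "le6"
    if ttr <= 12:
        return "m7_12"
    return "gt12"


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values at a declared processing stage."""

    values: pd.DataFrame
    stage: str = "tpm"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite expression values")
        if self.stage == "tpm" and (vals < 0).any():
            raise ValidationError("TPM matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], stage=self.stage)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], stage=self.stage)


@dataclass
class CohortTable:
    """One row per primary–recurrent pair, with clinical covariates.

    ``ttr_group`` is derived from ``ttr`` on construction and revalidated
    against the <=6 / 7–12 / >12 month boundaries if already present.
    """

    table: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in COHORT_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"cohort table missing mandatory columns: {missing}")
        if t["pair_id"].duplicated().any():
            raise ValidationError("duplicate pair_id values")
        for col in ("age", "ttr", "pfi"):
            t[col] = pd.to_numeric(t[col], errors="coerce")
        if (t["ttr"].dropna() <= 0).any():
            bad = t.loc[t["ttr"] <= 0, "pair_id"].tolist()
            raise ValidationError(f"non-positive TTR for pairs {bad[:5]}")
        derived = t["ttr"].map(ttr_group_of)
        if "ttr_group" in t.columns:
            stated = t["ttr_group"]
            clash = stated.notna() & derived.notna() & (stated != derived)
            if clash.any():
                raise ValidationError(
                    f"ttr_group inconsistent with ttr for pairs "
                    f"{t.loc[clash, 'pair_id'].tolist()[:5]}"
                )
        t["ttr_group"] = derived
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pair_ids(self) -> pd.Series:
        return self.table["pair_id"]

    @property
    def primary_ids(self) -> pd.Series:
        return self.table["sample_id_primary"]

    @property
    def recurrent_ids(self) -> pd.Series:
        return self.table["sample_id_recurrent"]

    def all_sample_ids(self) -> list[str]:
        return list(self.primary_ids) + list(self.recurrent_ids)

    def group(self, name: str) -> "CohortTable":
        """Restrict to one TTR stratum, or return self for ``'all'``."""
        if name == "all":
            return self
        if name not in TTR_GROUPS:
            raise ValueError(f"unknown TTR group {name!r}; expected 'all' or one of {TTR_GROUPS}")
        return CohortTable(self.table[self.table["ttr_group"] == name].copy())

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Check that every pair member resolves in an expression matrix."""
        known = set(expr.sample_ids)
        for col in ("sample_id_primary", "sample_id_recurrent"):
            unknown = [s for s in self.table[col] if s not in known]
            if unknown:
                raise ValidationError(
                    f"{col} values absent from expression matrix: {unknown[:5]}"
                )


@dataclass
class VariantTable:
    """Per-sample somatic variant calls with class labels and alt read counts."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "gene", "variant_class", "alt_read_count"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"variant table missing columns: {missing}")
        t = t.copy()
        t["alt_read_count"] = pd.to_numeric(t["alt_read_count"], errors="raise").astype(int)
        if (t["alt_read_count"] < 0).any():
            raise ValidationError("negative alt_read_count")
        bad = set(t["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValidationError(f"unknown variant classes: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TmbTable:
    """Per-sample tumor mutation burden, mutations per megabase."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("sample_id", "tmb") if c not in t.columns]
        if missing:
            raise ValidationError(f"TMB table missing columns: {missing}")
        t = t.copy()
        t["tmb"] = pd.to_numeric(t["tmb"], errors="raise")
        if (t["tmb"] < 0).any():
            raise ValidationError("negative TMB values")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in TMB table")
        self.table = t.reset_index(drop=True)

    def lookup(self, sample_ids) -> pd.Series:
        s = self.table.set_index("sample_id")["tmb"]
        missing = [x for x in sample_ids if x not in s.index]
        if missing:
            raise ValidationError(f"samples absent from TMB table: {missing[:5]}")
        return s.loc[list(sample_ids)]

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, **kw)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValidationError(f"failed to parse {path}: {exc}") from exc


def read_expression(path, stage: str = "tpm") -> ExpressionMatrix:
    """Read a gene × sample TSV (first column = gene id, header = sample ids)."""
    df = _read_tsv(path, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric expression cells in {path}: {exc}") from exc
    return ExpressionMatrix(df, stage=stage)


def write_expression(expr: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_cohort(path) -> CohortTable:
    return CohortTable(_read_tsv(path))


def write_cohort(cohort: CohortTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_variants(path) -> VariantTable:
    return VariantTable(_read_tsv(path))


def write_variants(variants: VariantTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    variants.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_tmb(path) -> TmbTable:
    return TmbTable(_read_tsv(path))


def write_tmb(tmb: TmbTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tmb.table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# cohort filtering


def filter_complete_pairs(cohort: CohortTable) -> CohortTable:
    """Retain IDH wild-type pairs with complete age, gender, data source and TTR.

    Mirrors the cohort-definition rule used to assemble paired-GBM training
    sets: IDH-mutant and IDH-unknown pairs are dropped, as is any pair missing
    one of the four mandatory covariates.  Removal counts by reason are stored
    on the result's ``filter_report`` and logged.  Idempotent.
    """
    t = cohort.table
    report: dict[str, int] = {"input": len(t)}
    is_wt = t["idh_status"] == "IDHwt"
    report["removed_not_idh_wt"] = int((~is_wt).sum())
    kept = t[is_wt]
    for col in ("age", "gender", "data_source", "ttr"):
        missing = kept[col].isna()
        report[f"removed_missing_{col}"] = int(missing.sum())
        kept = kept[~missing]
    report["retained"] = len(kept)
    if len(kept) == 0:
        logger.warning("filter_complete_pairs retained no pairs: %s", report)
    else:
        logger.info("filter_complete_pairs: %s", report)
    out = CohortTable(kept.copy(), filter_report=report)
    return out
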