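"""Shared fixtures: one moderately sized drift cohort and its adjusted
expression matrices, reused across the divergence/similarity/signature tests
to keep the suite fast."""

import warnings

import numpy as np
import pandas as pd
import pytest

import prgbm

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def drift_cohort():
    cfg = prgbm.SimulationConfig(n_pairs=60, n_genes=400, n_drift_genes=150, seed=11)
    return prgbm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def adjusted(drift_cohort):
    """Log-transformed and residualized matrices for the shared cohort."""
    c = drift_cohort
    merged = prgbm.ExpressionMatrix(
        pd.concat([c.tpm_primary.values, c.tpm_recurrent.values], axis=1), stage="tpm"
    )
    logx = prgbm.log_transform(prgbm.filter_expressed(merged))
    design = prgbm.CovariateDesign.from_cohort(c.cohort)
    return {
        "logx": logx,
        "design": design,
        # pair-adjusted residuals: input for paired DE / per-pair RMSE
        "resid_paired": prgbm.regress_out(logx, design),
        # patient-level residuals: input for similarity and survival analyses
        "resid_patient": prgbm.regress_out(logx, design, ["age", "gender", "data_source"]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
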