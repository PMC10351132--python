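import numpy as np
import pandas as pd
import pytest

from lncpath.io_core import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ClinicalTable,
    ExpressionMatrix,
    PurityVector,
)
from lncpath.synthetic_data import SimulationConfig, generate_cohort

SMALL_CFG = dict(
    n_samples=80,
    n_mrna=200,
    n_lncrna=40,
    pathway_size=30,
    n_true_lnc=5,
    n_risk_lnc=3,
    cox_betas=(1.2, -1.2, 1.0),
    immune_size=30,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(seed=7, **SMALL_CFG))


@pytest.fixture(scope="session")
def separated_cohort():
    """Cohort with strongly separated subtypes (large marker shift)."""
    return generate_cohort(SimulationConfig(seed=5, subtype_shift=4.0, **SMALL_CFG))


def make_expression(n_genes=6, n_samples=4, seed=0, n_lnc=2):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{i}" for i in range(n_samples)]
    values = pd.DataFrame(rng.normal(5, 1, (n_genes, n_samples)), index=genes, columns=samples)
    biotype = pd.Series(
        [BIOTYPE_LNCRNA] * n_lnc + [BIOTYPE_MRNA] * (n_genes - n_lnc), index=genes
    )
    return ExpressionMatrix(values, biotype)


def make_clinical(n=10, seed=0, frac_events=0.7):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time": rng.exponential(1000, n) + 1,
                "os_status": (rng.random(n) < frac_events).astype(int),
            },
            index=pd.Index(samples, name="sample"),
        )
    )


def make_purity(sample_ids, seed=0):
    rng = np.random.default_rng(seed)
    return PurityVector(pd.Series(rng.beta(5, 2, len(sample_ids)), index=list(sample_ids)))
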