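import numpy as np
import pandas as pd
import pytest

from hepascreen import ExpressionMatrix, default_registry, paper_mimic_cohort
from hepascreen.simulate import CohortConfig, generate_cohort

MIMIC_SEED = 17


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def mimic_cohort():
    """The default study-mimicking cohort at the packaged master seed."""
    return paper_mimic_cohort(MIMIC_SEED)


@pytest.fixture(scope="session")
def mimic_expr(mimic_cohort):
    return mimic_cohort[1]


@pytest.fixture(scope="session")
def mimic_truth(mimic_cohort):
    return mimic_cohort[2]


@pytest.fixture()
def small_config():
    return CohortConfig(
        n_per_group={"NOR": 3, "CIR": 3, "HCC_EARLY": 3, "HCC_LATE": 3},
        n_genes=20, probes_per_gene=3, master_seed=5,
    )


@pytest.fixture()
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def bias_cohort():
    """Single-probe fixture with planted covariate bias of amplitude 1.0 on
    all three covariates plus 2x group effects on the first tenth of genes."""
    genes = [f"G{i:04d}" for i in range(8000)]
    cfg = CohortConfig(
        n_per_group={"NOR": 4, "CIR": 4, "HCC_EARLY": 4, "HCC_LATE": 4},
        genes=genes, probes_per_gene=1, baseline_log2_sd=0.4, noise_log2_sd=0.2,
        group_effects={g: {"CIR": 2.0, "HCC": 2.0} for g in genes[:800]},
        bias_amplitudes={"gc_fraction": 1.0, "melting_temp": 1.0,
                         "position_index": 1.0},
        master_seed=202,
    )
    return generate_cohort(cfg)


def make_expression(values: np.ndarray, groups=None, genes=None) -> ExpressionMatrix:
    """Small helper for hand-built matrices (linear scale)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    g = pd.Series(groups, index=samples) if groups is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), g)
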