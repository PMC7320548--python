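import numpy as np
import pandas as pd
import pytest

from igfresponse.datatypes import AbundanceMatrix, SampleMetadata
from igfresponse.simulate import SimulationConfig, simulate_dataset


def make_matrix(values, kind="counts", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=genes, columns=samples), kind)


def make_metadata(samples, treatments, patients=None, diagnosis=None, **covariates):
    n = len(samples)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": patients or [f"p{i // 2}" for i in range(n)],
            "diagnosis": diagnosis or ["CTL"] * n,
            "treatment": treatments,
            "replicate": [1 + i % 2 for i in range(n)],
        }
    )
    for k, v in covariates.items():
        df[k] = v
    return SampleMetadata(df)


def two_group_counts(rng, n_genes=400, n_per_group=6, phi=0.15, mu_range=(2, 8),
                     de_frac=0.0, logfc=0.0):
    """NB count matrix for a plain two-group design with optional planted DE."""
    mu = 2.0 ** rng.uniform(*mu_range, n_genes)
    n = 2 * n_per_group
    m = np.tile(mu[:, None], (1, n))
    n_de = int(de_frac * n_genes)
    direction = rng.choice([-1.0, 1.0], size=n_de)
    if n_de:
        m[:n_de, n_per_group:] *= 2.0 ** (direction[:, None] * logfc)
    r = 1.0 / phi
    y = rng.negative_binomial(r, r / (r + m)).astype(float)
    matrix = make_matrix(y)
    meta = make_metadata(
        list(matrix.sample_ids),
        ["H2O"] * n_per_group + ["acute"] * n_per_group,
    )
    truth_de = np.zeros(n_genes, dtype=bool)
    truth_de[:n_de] = True
    return matrix, meta, truth_de, direction


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared by unit tests (fast but non-trivial)."""
    return simulate_dataset(
        SimulationConfig(n_genes=800, seed=7, library_size_range=(200_000, 300_000))
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with effect 1.5, used by recovery-style checks."""
    return simulate_dataset(
        SimulationConfig(
            n_genes=800, seed=11, effect_logfc=1.5, baseline_logfc=1.5,
            library_size_range=(200_000, 300_000),
        )
    )
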