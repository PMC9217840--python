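import numpy as np
import pandas as pd
import pytest

from svzm.preprocess import MethylationMatrix
from svzm.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest training-design cohort (24+30 samples, 2000 CpGs, 60 planted
    DMPs) shared across tests that only read it."""
    cfg = SimulationConfig(seed=42, n_probes=2000, n_dmp=60, n_genes=60, n_coupled=30)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mri_labels(small_cohort):
    return small_cohort.samples.set_index("sample_id")["mri_label"]


@pytest.fixture
def tiny_matrix():
    """Hand-sized methylation matrix with annotation flags for filter tests."""
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(10, 6)),
        index=[f"cg{i:02d}" for i in range(10)],
        columns=[f"S{i}" for i in range(6)],
    )
    ann = pd.DataFrame(
        {
            "chrom": ["chrX"] * 2 + ["chr1"] * 8,
            "pos": np.arange(10) * 100,
            "gene": ["GA"] * 5 + [""] * 5,
            "sex_chrom": [True, True] + [False] * 8,
            "snp_overlap": [False] * 5 + [True] + [False] * 4,
            "repetitive": [False] * 5 + [True] + [False] * 4,
        },
        index=beta.index,
    )
    return MethylationMatrix(beta, ann)
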