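import numpy as np
import pandas as pd
import pytest

import episcape as ep


def toy_table(site_values: dict[str, list[float]], tissues: list[str]) -> tuple[ep.MethylationMatrix, pd.DataFrame]:
    """Build a matrix + metadata from per-site value lists.

    ``tissues`` gives the tissue of each column; group defaults to
    'control'.
    """
    samples = [f"s{i:02d}" for i in range(len(tissues))]
    df = pd.DataFrame.from_dict(site_values, orient="index", columns=samples)
    df.index.name = "site_id"
    meta = pd.DataFrame({
        "sample_id": samples,
        "tissue": tissues,
        "group": ["control"] * len(samples),
    }).set_index("sample_id")
    return ep.MethylationMatrix(df), meta


@pytest.fixture(scope="session")
def small_cohort():
    """4 tissues x (10+10) samples, 2000 sites, 20 planted per tissue,
    no erosion, 1% missing — the default substrate for recovery tests."""
    cfg = ep.SyntheticConfig(
        n_tissues=4, samples_per_tissue_per_group=10, n_sites=2000,
        n_unique_per_tissue=20, concentration=50, erosion_lambda=0.0,
        missing_rate=0.01, seed=11,
    )
    matrix, meta, truth = ep.generate_multitissue(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def eroded_cohort():
    """Same shape but with a strong case-group erosion (lambda = 0.8)."""
    cfg = ep.SyntheticConfig(
        n_tissues=4, samples_per_tissue_per_group=10, n_sites=2000,
        n_unique_per_tissue=20, concentration=50, erosion_lambda=0.8,
        missing_rate=0.0, seed=12,
    )
    matrix, meta, truth = ep.generate_multitissue(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
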