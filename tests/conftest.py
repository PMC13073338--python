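import numpy as np
import pandas as pd
import pytest

import stratomics as st


@pytest.fixture(scope="session")
def small_cohort():
    """One-stratum cohort with planted shared effects, plus its normalized
    (per-SD) matrix and split — shared across association tests."""
    cfg = st.SyntheticConfig(
        n_samples_per_stratum=250, case_fraction=0.4, strata=("33",),
        n_analytes=80, frac_shared_effects=0.25, frac_stratum_specific=0.0,
        frac_opposite=0.0, effect_size_logodds=0.8, seed=42,
    )
    matrix, meta, truth = st.generate_cohort(cfg)
    norm = st.log10_normalize(matrix)
    norm = st.remove_batch_effect(norm, meta["batch"])
    norm = st.merge_and_standardize([norm], zscore=True)
    split = st.split_cohort(meta, seed=42)
    return matrix, meta, truth, norm, split


@pytest.fixture(scope="session")
def qc_fixture():
    return st.generate_qc_fixture(st.SyntheticConfig(seed=7))


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 10.0, 100.0], [2.0, 20.0, 200.0]],
        index=["A1", "A2"], columns=["S1", "S2", "S3"],
    )
    return st.AnalyteMatrix(data)


@pytest.fixture()
def toy_metadata():
    rng = np.random.default_rng(0)
    n = 40
    meta = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "status": ["AD"] * (n // 2) + ["CO"] * (n // 2),
        "age": rng.normal(72, 6, n).round(1),
        "sex": ["M", "F"] * (n // 2),
        "stratum": ["33"] * n,
        "batch": ["b1", "b2"] * (n // 2),
    })
    return meta.set_index("sample_id", drop=False)
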