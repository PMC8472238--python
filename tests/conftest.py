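import dataclasses

import numpy as np
import pandas as pd
import pytest

import metaroast as mr


@pytest.fixture
def tiny_matrix():
    """4 features x 4 samples, one missing cell, two platforms."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 2.0, 10.0],
            "s2": [2.0, 5.0, np.nan, 12.0],
            "s3": [3.0, 6.0, 4.0, 14.0],
            "s4": [4.0, 7.0, 5.0, 16.0],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    values.index.name = "feature_id"
    platform = pd.Series(
        ["uplc_pos", "uplc_pos", "uplc_pos", "gcms"], index=values.index, name="platform"
    )
    return mr.FeatureMatrix(values, platform)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-spec synthetic dataset shared across tests."""
    return mr.generate_dataset(mr.SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Preprocessed matrix + per-feature statistics for the shared dataset."""
    fm, samples, ann, db, truth = default_dataset
    nm = mr.preprocess(fm)
    stats, prior, design = mr.differential_analysis(nm, samples)
    return nm, samples, ann, db, truth, stats, prior, design


def make_spec(**overrides) -> mr.SyntheticSpec:
    return dataclasses.replace(mr.SyntheticSpec(), **overrides)
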