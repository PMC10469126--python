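from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import danger
from danger import ClassifierConfig, ScanConfig, analyze_dataset, make_fixture


def random_contigs(rng: np.random.Generator, n: int, length: int, prefix="ctg"):
    return [
        (f"{prefix}_{i}", "".join(rng.choice(list("ACGT"), size=length)))
        for i in range(n)
    ]


def analyze_fixture(ds, criterion="dTPM", max_mm=8, pam="NGG", t=0.4, alpha=0.001):
    """Full in-memory analysis of a synthetic dataset."""
    return analyze_dataset(
        ds.transcriptome,
        ds.truth.guide,
        ds.expression,
        ds.gene_map,
        ds.annotations,
        ScanConfig(max_mm=max_mm, pam_pattern=pam),
        ClassifierConfig(t=t, alpha=alpha),
        criterion=criterion,
        de_table=ds.de_table,
    )


@pytest.fixture(scope="session")
def strong_dataset():
    return make_fixture("strong", seed=11)


@pytest.fixture(scope="session")
def mixed_dataset():
    return make_fixture("mixed", seed=23)


@pytest.fixture(scope="session")
def strong_analysis(strong_dataset):
    return analyze_fixture(strong_dataset)


@pytest.fixture(scope="session")
def mixed_analysis(mixed_dataset):
    return analyze_fixture(mixed_dataset)


@pytest.fixture
def guide():
    return danger.DEFAULT_GUIDE


@pytest.fixture
def small_screen():
    return pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3", "t4"],
            "mean_wt": [10.0, 10.0, 10.0, 0.0],
            "mean_edited": [2.0, 9.0, 3.9, 5.0],
            "tpm_ratio": [0.2, 0.9, 0.39, np.nan],
            "dtpm": [True, False, True, False],
            "m_value": [-2.0, 0.1, -1.0, 1.0],
            "p_value": [1e-5, 0.5, 0.0005, 0.9],
            "dde": [True, False, True, False],
        }
    )
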