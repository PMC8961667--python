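"""Shared fixtures: the bundled registry, small deterministic matrices, and
session-scoped synthetic cohorts reused by the cohort-level tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from emtmet.io import ExpressionMatrix
from emtmet.pipeline import score_dataset
from emtmet.signatures import load_registry
from emtmet.synth import SyntheticConfig, generate_cohort, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def toy_matrix():
    """6 genes x 4 samples, deterministic values."""
    rng = np.random.default_rng(7)
    genes = ["CDH1", "G1", "G2", "G3", "G4", "G5"]
    frame = pd.DataFrame(
        rng.normal(8.0, 2.0, (6, 4)),
        index=genes,
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame, dataset_id="toy")


@pytest.fixture(scope="session")
def sign_dataset(registry):
    """One dataset at the sign-recovery study conditions.

    n = 100 samples, EMT coupling 1.0, noise sigma 0.5.
    """
    config = SyntheticConfig(n_samples=100, seed=11, emt_coupling=1.0, noise_sigma=0.5)
    return generate_dataset(config, registry)


@pytest.fixture(scope="session")
def recovery_cohort(registry):
    """50 datasets x 60 samples with glycolysis +0.8 / OXPHOS -0.8 / FAO -0.8."""
    base = SyntheticConfig(
        n_samples=60,
        couplings={"glycolysis": 0.8, "oxphos": -0.8, "fao": -0.8},
    )
    return generate_cohort(50, seed=23, base_config=base, registry=registry)


@pytest.fixture(scope="session")
def recovery_tables(recovery_cohort, registry):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [score_dataset(m, registry) for m, _ in recovery_cohort]
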