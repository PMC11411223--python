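"""Shared fixtures: small seeded synthetic datasets reused across tests."""

import numpy as np
import pytest

from sepsistraj import (SimConfig, build_cohort, build_matrix, generate,
                        label_cohort)


@pytest.fixture(scope="session")
def mixed_bundles():
    """300 patients, 15% with a planted inclusion violation."""
    cfg = SimConfig(n_patients=300, seed=11, ineligible_fraction=0.15)
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_bundles():
    """400 fully eligible patients, no observation missingness."""
    cfg = SimConfig(n_patients=400, seed=5, ineligible_fraction=0.0,
                    missingness_rate=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def modelling_data():
    """Labeled feature matrix for model/conformal tests (n=900)."""
    cfg = SimConfig(n_patients=900, seed=2, ineligible_fraction=0.0)
    bundles, truth = generate(cfg)
    cohort = build_cohort(bundles)
    labeled, _ = label_cohort(cohort, bundles)
    matrix = build_matrix(labeled, bundles)
    y = (labeled.set_index("patient_id")
         .loc[matrix.patient_ids, "trajectory"].to_numpy(dtype=int))
    return matrix, y


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
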