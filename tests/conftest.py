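"""Shared fixtures: profile builders and small seeded cohorts."""

import numpy as np
import pytest

from kepsolve import CohortParams, DonorProfile, RecipientProfile, WeightConfig, generate_cohort


def make_donor(a=("A23",), b=(), dr=(), dq=(), abo="O", age=40, sex="M", weight=80.0):
    return DonorProfile(
        antigens={"A": frozenset(a), "B": frozenset(b),
                  "DR": frozenset(dr), "DQ": frozenset(dq)},
        abo=abo, age=age, sex=sex, weight_kg=weight,
    )


def make_recipient(a=("A66",), b=(), dr=(), dq=(), antibodies=(), abo="O",
                   age=40, sex="M", weight=80.0):
    return RecipientProfile(
        antigens={"A": frozenset(a), "B": frozenset(b),
                  "DR": frozenset(dr), "DQ": frozenset(dq)},
        antibodies=frozenset(antibodies),
        abo=abo, age=age, sex=sex, weight_kg=weight,
    )


@pytest.fixture
def cfg():
    return WeightConfig()


@pytest.fixture
def small_cohort():
    return generate_cohort(CohortParams(n_pairs=5, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
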