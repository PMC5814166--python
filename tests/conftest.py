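"""Shared fixtures: configs, small populations, random dataset factories."""

import math

import numpy as np
import pytest

from lifemarket.records import (
    BiomedicalRecord,
    Dataset,
    RecordTypeSpec,
    UserProfile,
    ValuationConfig,
)
from lifemarket.synthetic import default_config


@pytest.fixture
def config() -> ValuationConfig:
    """Default registry: genome (static), four dynamic types, sparse synergies."""
    return default_config()


@pytest.fixture
def plain_config() -> ValuationConfig:
    """Single finite-half-life type with unit base value; no synergies."""
    return ValuationConfig(
        type_registry={
            "unit": RecordTypeSpec(type_key="unit", base_value=1.0, half_life=1.0)
        },
        relationship_regularization=False,
    )


@pytest.fixture
def user() -> UserProfile:
    return UserProfile(user_id="u1", current_age=60.0)


def make_random_dataset(rng: np.random.Generator, config, n_users=4, max_records=3,
                        zero_quality_prob=0.1):
    """Random dataset + matching user map drawn from the config's registry."""
    types = sorted(config.type_registry)
    users = {}
    ds = Dataset()
    rid = 0
    for i in range(n_users):
        uid = f"u{i}"
        users[uid] = UserProfile(user_id=uid, current_age=80.0)
        for _ in range(int(rng.integers(1, max_records + 1))):
            q = 0.0 if rng.random() < zero_quality_prob else float(rng.uniform(0.2, 2.0))
            ds.add(BiomedicalRecord(
                record_id=f"r{rid}",
                owner_id=uid,
                type=types[int(rng.integers(0, len(types)))],
                time=float(rng.uniform(0.0, 70.0)),
                quality=q,
            ))
            rid += 1
    return ds, users


@pytest.fixture
def random_dataset_factory(config):
    def factory(seed: int, **kwargs):
        return make_random_dataset(np.random.default_rng(seed), config, **kwargs)

    return factory
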