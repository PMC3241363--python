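import numpy as np
import pytest

from metadx import Group, SimConfig, generate_cohort


def random_centered_instance(rng, n=30, d=50):
    """Random column-centered X and centered +/-1 response."""
    X = rng.normal(size=(n, d))
    X -= X.mean(axis=0)
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    while len(set(y)) < 2:
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    return X, y - y.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(20110208)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (21 RA / 9 control / 17 PsoA)."""
    return generate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def ra_control_subset(default_cohort):
    table, meta = default_cohort
    keep = [m.sample_id for m in meta if m.group in (Group.RA, Group.CONTROL)]
    sub = table.subset_samples(keep)
    sub_meta = [m for m in meta if m.sample_id in set(keep)]
    return sub, sub_meta
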