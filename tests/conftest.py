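import numpy as np
import pytest

from mptbridge import (
    LatentTraitModel,
    generate_dataset,
    pair_clustering_fixture,
    parse_eqn,
)
from mptbridge.synthetic import PAIR_CLUSTERING_EQN


@pytest.fixture(scope="session")
def pc_spec_full():
    """Pair-clustering spec with all four parameters (c, r, u, a)."""
    return parse_eqn(PAIR_CLUSTERING_EQN, name="pair_clustering")


@pytest.fixture(scope="session")
def pc_spec(pc_spec_full):
    """Pair-clustering spec with the usual a = u constraint (P = 3)."""
    return pc_spec_full.apply_constraints({"a": "u"})


@pytest.fixture(scope="session")
def binomial_spec():
    """One-parameter binomial tree: recalled vs not recalled."""
    return parse_eqn("1 hit p\n1 miss (1-p)\n", name="binomial")


@pytest.fixture(scope="session")
def small_pc_dataset():
    """A small two-trial pair-clustering dataset with known ground truth."""
    spec, model, defaults = pair_clustering_fixture(I=8)
    table, truth = generate_dataset(
        model,
        mu=defaults["mu"],
        xi=defaults["xi"],
        delta=defaults["delta"],
        J=defaults["J"],
        seed=1234,
    )
    return spec, model, table, truth
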