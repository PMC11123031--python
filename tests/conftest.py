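import numpy as np
import pytest

from pathpair import (
    FeatureDescriptor,
    FeatureMatrix,
    PathwayMembership,
    SimConfig,
    simulate,
)


def make_matrix(values, bond_levels=None, entity_kind="metabolite", names=None, ids=None):
    """Small helper to build a FeatureMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if bond_levels is None:
        bond_levels = [0] * k
    if names is None:
        names = [f"f{j}" for j in range(k)]
    if ids is None:
        ids = [f"e{i}" for i in range(n)]
    descriptors = [
        FeatureDescriptor(name=nm, bond_level=bl, entity_kind=entity_kind)
        for nm, bl in zip(names, bond_levels)
    ]
    return FeatureMatrix(entry_ids=list(ids), descriptors=descriptors, values=values)


@pytest.fixture
def tiny_matrix():
    """Two metabolites, three features across two bond levels."""
    return make_matrix([[1, 2, 3], [4, 5, 6]], bond_levels=[0, 0, 1])


@pytest.fixture
def tiny_membership():
    return PathwayMembership({"P1": {"e0", "e1"}, "P2": {"e1"}})


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal dataset shared by fast model tests."""
    config = SimConfig(n_metabolites=150, n_pathways=4, seed=42)
    return simulate(config)
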