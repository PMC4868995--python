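import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")

from gravipath.dataio import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
)
from gravipath.ranking import RankedGeneList


@pytest.fixture
def tiny_dataset():
    """4 genes x 6 samples, two triplicate groups, non-negative values."""
    rng = np.random.default_rng(7)
    values = rng.uniform(50, 150, size=(4, 6))
    return ExpressionDataset(
        ["gA", "gB", "gC", "gD"],
        [f"s{i}" for i in range(6)],
        values,
        ["descA", "descB", "descC", "descD"],
    )


@pytest.fixture
def tiny_labels():
    return PhenotypeLabels(
        ["ug", "ug", "ug", "g1", "g1", "g1"], ("ug", "g1")
    )


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        [
            GeneSet("S1", "first", ("gA", "gB")),
            GeneSet("S2", "second", ("gC", "gD")),
        ],
        module="test_sets",
    )


@pytest.fixture
def five_gene_rgl():
    """The worked running-sum example: metrics (3, 2, 1, -1, -2)."""
    return RankedGeneList(
        ["g1", "g2", "g3", "g4", "g5"], np.array([3.0, 2.0, 1.0, -1.0, -2.0])
    )


def random_rgl(rng, n):
    r = np.sort(rng.normal(size=n))[::-1]
    return RankedGeneList([f"g{i}" for i in range(n)], r)
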