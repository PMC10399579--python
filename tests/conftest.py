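import warnings

import numpy as np
import pytest

from immunanno import (
    ExpressionMatrix,
    GeneSet,
    SimulationConfig,
    build_hierarchy,
    make_fixture_hierarchy,
    simulate_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # small fixtures trip the "<3 genes" stability warning by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fewer than 3 genes.*")
        warnings.filterwarnings("ignore", message=".*absent from the matrix.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x 3 cells with distinct values per cell (tie-free)."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        cell_barcodes=["c1", "c2", "c3"],
        counts=np.array(
            [[10.0, 1.0, 3.0], [5.0, 2.0, 9.0], [2.0, 4.0, 6.0], [1.0, 8.0, 2.0]]
        ),
    )


@pytest.fixture
def two_type_hierarchy():
    """Depth-1 hierarchy with two disjoint 3-gene types plus a pre-screen pair."""
    sets = [
        GeneSet("A", ["a1", "a2", "a3"]),
        GeneSet("B", ["b1", "b2", "b3"]),
        GeneSet("Immune", ["i1", "i2", "i3"]),
        GeneSet("Non_immune", ["n1", "n2", "n3"]),
    ]
    return build_hierarchy(sets, {"A": [], "B": []}, ("Immune", "Non_immune"))


@pytest.fixture(scope="session")
def nested_fixture_hierarchy():
    """2 majors, one with 2 children, one child with 2 grandchildren."""
    return make_fixture_hierarchy(
        n_major=2, n_children={"M1": 2, "M1_1": 2}, genes_per_set=8
    )


@pytest.fixture(scope="session")
def nested_dataset(nested_fixture_hierarchy):
    cfg = SimulationConfig(
        hierarchy=nested_fixture_hierarchy,
        cells_per_leaf=60,
        n_background_genes=80,
        marker_fold_change=8.0,
        seed=7,
    )
    return simulate_dataset(cfg)
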