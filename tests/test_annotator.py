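import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from immunanno import (
    ConfigError,
    ExpressionMatrix,
    GeneSet,
    HierarchicalAnnotator,
    InputError,
    SimulationConfig,
    annotate_hierarchical,
    annotate_layer,
    build_hierarchy,
    make_fixture_hierarchy,
    prescreen_immune,
    simulate_dataset,
)


def matrix_from(genes, columns):
    """columns: dict barcode -> dict gene -> value (missing = 0)."""
    X = np.zeros((len(genes), len(columns)))
    for j, (_, vals) in enumerate(columns.items()):
        for g, v in vals.items():
            X[genes.index(g), j] = v
    return ExpressionMatrix(genes, list(columns), X)


@pytest.fixture
def prescreen_matrix(two_type_hierarchy):
    genes = ["a1", "a2", "a3", "b1", "b2", "b3", "i1", "i2", "i3", "n1", "n2", "n3"]
    return matrix_from(
        genes,
        {
            "immune_cell": {"i1": 9, "i2": 8, "i3": 7, "a1": 5},
            "stromal_cell": {"n1": 9, "n2": 8, "n3": 7},
            "empty_cell": {},
        },
    )


class TestPrescreen:
    def test_labels(self, two_type_hierarchy, prescreen_matrix):
        labels = prescreen_immune(prescreen_matrix, two_type_hierarchy)
        assert labels["immune_cell"] == "immune"
        assert labels["stromal_cell"] == "non_immune"
        assert labels["empty_cell"] == "unassigned"

    def test_missing_prescreen_pair_is_config_error(self, prescreen_matrix):
        sets = [GeneSet("A", ["a1"]), GeneSet("B", ["b1"])]
        h = build_hierarchy(sets, {"A": [], "B": []})  # no prescreen pair
        with pytest.raises(ConfigError, match="pre-?screen"):
            prescreen_immune(prescreen_matrix, h)

    def test_unscorable_prescreen_set_is_config_error(self, two_type_hierarchy):
        m = matrix_from(["i1", "i2", "x1"], {"c1": {"i1": 3}, "c2": {"x1": 1}})
        with pytest.raises(ConfigError, match="Non_immune"):
            prescreen_immune(m, two_type_hierarchy)


class TestAnnotateLayer:
    def test_dominant_signal(self):
        sets = [GeneSet("CD4_T", ["cd4a", "cd4b"]), GeneSet("CD8_T", ["cd8a", "cd8b"])]
        m = matrix_from(
            ["cd4a", "cd4b", "cd8a", "cd8b", "bg"],
            {"cell": {"cd8a": 9, "cd8b": 8, "bg": 1}},
        )
        out = annotate_layer(m, sets, ["cell"])
        assert out.label.iloc[0] == "CD8_T" and out.margin.iloc[0] > 0

    def test_symmetric_tie_goes_to_first_declared_set_with_zero_margin(self):
        # at alpha=0 the walk positions {1,4} and {2,3} contribute equally,
        # so the two equal-size sets tie exactly and the declared order wins
        from immunanno import SsgseaParams

        sets = [GeneSet("P", ["p1", "p2"]), GeneSet("Q", ["q1", "q2"])]
        m = matrix_from(
            ["p1", "q1", "q2", "p2"],
            {"cell": {"p1": 4, "q1": 3, "q2": 2, "p2": 1}},
        )
        out = annotate_layer(m, sets, ["cell"], SsgseaParams(alpha=0.0))
        assert out.label.iloc[0] == "P"
        assert out.margin.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_on_synthetic_pair(self):
        h = make_fixture_hierarchy(n_major=2, genes_per_set=10, prescreen=False)
        ds = simulate_dataset(
            SimulationConfig(
                hierarchy=h, cells_per_leaf=250, n_background_genes=100,
                marker_fold_change=8.0, seed=11, n_nonimmune=0,
            )
        )
        sets = [n.gene_set for n in h.roots]
        out = annotate_layer(ds.matrix, sets, ds.matrix.cell_barcodes)
        truth = ds.truth.set_index("barcode").loc[out.barcode, "layer1"]
        assert (out.label.to_numpy() == truth.to_numpy()).mean() >= 0.95

    def test_contract_errors(self, small_matrix):
        with pytest.raises(InputError):
            annotate_layer(small_matrix, [GeneSet("S", ["g1"])], ["c1"])
        with pytest.raises(InputError):
            annotate_layer(
                small_matrix, [GeneSet("S", ["g1"]), GeneSet("R", ["g2"])], []
            )


class TestAnnotateHierarchical:
    def test_depth_one_tree_gives_only_layer1(self, two_type_hierarchy, prescreen_matrix):
        res = annotate_hierarchical(prescreen_matrix, two_type_hierarchy)
        row = res.frame.set_index("barcode").loc["immune_cell"]
        assert row["layer1_label"] == "A"
        assert row["layer2_label"] is None and row["layer3_label"] is None

    def test_nonimmune_and_zero_cells_get_no_layer_labels(
        self, two_type_hierarchy, prescreen_matrix
    ):
        res = annotate_hierarchical(prescreen_matrix, two_type_hierarchy)
        df = res.frame.set_index("barcode")
        for bc in ("stromal_cell", "empty_cell"):
            assert all(df.loc[bc, f"layer{k}_label"] is None for k in (1, 2, 3))

    def test_leaf_types_stop_deepening(self, nested_dataset, nested_fixture_hierarchy):
        res = annotate_hierarchical(nested_dataset.matrix, nested_fixture_hierarchy)
        df = res.frame
        leaf_l1 = df[df.layer1_label == "M2"]  # M2 has no children
        assert len(leaf_l1) > 0
        assert all(l is None for l in leaf_l1.layer2_label)

    def test_hierarchical_consistency_and_recovery(
        self, nested_dataset, nested_fixture_hierarchy
    ):
        h = nested_fixture_hierarchy
        res = annotate_hierarchical(nested_dataset.matrix, h)
        res.check_consistency(h)  # raises on any parent-child violation
        truth = nested_dataset.truth.set_index("barcode")
        df = res.frame.set_index("barcode")
        for k in (1, 2, 3):
            mask = truth[f"layer{k}"].notna()
            agree = (
                df.loc[mask.index[mask], f"layer{k}_label"]
                == truth.loc[mask, f"layer{k}"]
            ).mean()
            assert agree >= 0.95

    def test_max_layer_truncates(self, nested_dataset, nested_fixture_hierarchy):
        res = annotate_hierarchical(
            nested_dataset.matrix, nested_fixture_hierarchy, max_layer=1
        )
        assert res.frame.layer1_label.notna().any()
        assert all(l is None for l in res.frame.layer2_label)

    def test_subsetting_stability(self, nested_dataset, nested_fixture_hierarchy):
        # labels are per-cell quantities: a subset annotates identically
        m = nested_dataset.matrix
        full = annotate_hierarchical(m, nested_fixture_hierarchy).frame.set_index("barcode")
        pick = list(m.cell_barcodes[::7])
        sub = annotate_hierarchical(
            m.subset_cells(pick), nested_fixture_hierarchy
        ).frame.set_index("barcode")
        for col in ("prescreen_label", "layer1_label", "layer2_label", "layer3_label"):
            assert list(sub[col]) == list(full.loc[pick, col])

    def test_permutation_invariance_tie_free(self, rng, two_type_hierarchy):
        genes = ["a1", "a2", "a3", "b1", "b2", "b3", "i1", "i2", "i3", "n1", "n2", "n3"]
        X = rng.permutation(np.arange(1.0, 1 + len(genes) * 4)).reshape(len(genes), 4)
        m = ExpressionMatrix(genes, [f"c{i}" for i in range(4)], X)
        base = annotate_hierarchical(m, two_type_hierarchy).frame.set_index("barcode")
        gperm = rng.permutation(len(genes))
        cperm = rng.permutation(4)
        m2 = ExpressionMatrix(
            [genes[i] for i in gperm],
            [f"c{i}" for i in cperm],
            X[np.ix_(gperm, cperm)],
        )
        perm = annotate_hierarchical(m2, two_type_hierarchy).frame.set_index("barcode")
        for bc in base.index:
            assert perm.loc[bc, "layer1_label"] == base.loc[bc, "layer1_label"]
            assert perm.loc[bc, "prescreen_label"] == base.loc[bc, "prescreen_label"]

    def test_label_invariance_under_log1p(self, nested_dataset, nested_fixture_hierarchy):
        m = nested_dataset.matrix
        m_log = ExpressionMatrix(m.gene_ids, m.cell_barcodes, np.log1p(m.dense()))
        a = annotate_hierarchical(m, nested_fixture_hierarchy).frame
        b = annotate_hierarchical(m_log, nested_fixture_hierarchy).frame
        for col in ("prescreen_label", "layer1_label", "layer2_label", "layer3_label"):
            assert list(a[col]) == list(b[col])

    def test_no_prescreen_annotates_everything_nonzero(
        self, two_type_hierarchy, prescreen_matrix
    ):
        res = annotate_hierarchical(
            prescreen_matrix, two_type_hierarchy, prescreen=False
        )
        df = res.frame.set_index("barcode")
        assert df.loc["stromal_cell", "layer1_label"] in ("A", "B")
        assert df.loc["empty_cell", "prescreen_label"] == "unassigned"
        assert df.loc["empty_cell", "layer1_label"] is None

    def test_min_margin_withholds_close_calls(self, nested_dataset, nested_fixture_hierarchy):
        res = annotate_hierarchical(
            nested_dataset.matrix, nested_fixture_hierarchy, min_margin=1e9
        )
        assert all(l is None for l in res.frame.layer1_label)


class TestEstimatorContract:
    def test_clone_fit_predict(self, nested_dataset, nested_fixture_hierarchy):
        m = nested_dataset.matrix
        ann = HierarchicalAnnotator(
            hierarchy=nested_fixture_hierarchy, gene_names=m.gene_ids, max_layer=1
        )
        ann = clone(ann)
        X = m.cells_by_genes()
        labels = ann.fit(X).predict(X)
        assert labels.shape == (m.n_cells,)
        assert set(labels) <= set(ann.classes_)

    def test_invalid_max_layer(self, small_matrix, two_type_hierarchy):
        ann = HierarchicalAnnotator(
            hierarchy=two_type_hierarchy, gene_names=small_matrix.gene_ids, max_layer=5
        )
        with pytest.raises(InputError):
            ann.fit(small_matrix.cells_by_genes())

    def test_gene_count_mismatch(self, small_matrix, two_type_hierarchy):
        ann = HierarchicalAnnotator(
            hierarchy=two_type_hierarchy, gene_names=["x", "y"]
        )
        with pytest.raises(InputError):
            ann.fit(small_matrix.cells_by_genes())
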