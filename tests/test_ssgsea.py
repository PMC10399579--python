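import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from immunanno import (
    GeneSet,
    InputError,
    ScoringError,
    SsgseaParams,
    SsgseaScorer,
    enrichment_score,
    rank_genes,
    score_matrix,
)

from _oracle import oracle_es, oracle_ranks, oracle_score_matrix


class TestRankGenes:
    def test_strictly_ordered(self):
        np.testing.assert_array_equal(rank_genes([10, 5, 2, 1]), [4, 3, 2, 1])

    def test_ties_average(self):
        np.testing.assert_array_equal(rank_genes([7, 7], "average"), [1.5, 1.5])

    def test_ties_ordinal_ascending_index_gets_lower_rank(self):
        np.testing.assert_array_equal(rank_genes([7, 7], "ordinal"), [1, 2])

    def test_too_short(self):
        with pytest.raises(InputError):
            rank_genes([1.0])

    def test_matches_oracle_ranks(self, rng):
        for method in ("average", "ordinal"):
            x = rng.integers(0, 4, size=30).astype(float)
            np.testing.assert_allclose(rank_genes(x, method), oracle_ranks(list(x), method))


class TestEnrichmentScore:
    def test_singleton_top_set_is_plus_one(self):
        for alpha in (0.0, 0.25, 1.0):
            es = enrichment_score(rank_genes([5, 1]), [0], SsgseaParams(alpha=alpha))
            assert es == pytest.approx(1.0)

    def test_singleton_bottom_set_is_minus_one(self):
        for alpha in (0.0, 0.25, 1.0):
            es = enrichment_score(rank_genes([5, 1]), [1], SsgseaParams(alpha=alpha))
            assert es == pytest.approx(-1.0)

    def test_worked_example(self):
        # expression (10,5,2,1), S={g1,g3}, alpha=0.25: frozen from the oracle
        ranks = rank_genes([10, 5, 2, 1])
        es = enrichment_score(ranks, np.array([True, False, True, False]))
        assert es == pytest.approx(1.0864272337258903, abs=1e-12)
        assert es == pytest.approx(oracle_es([10, 5, 2, 1], [0, 2]), abs=1e-12)

    def test_empty_overlap_is_scoring_error(self):
        with pytest.raises(ScoringError):
            enrichment_score(rank_genes([3, 2, 1]), [])

    def test_full_set_rejected(self):
        with pytest.raises(InputError):
            enrichment_score(rank_genes([3, 2, 1]), [0, 1, 2])

    def test_antisymmetry_under_complement_at_alpha_zero(self, rng):
        x = rng.permutation(10).astype(float)  # tie-free, N=10
        ranks = rank_genes(x)
        s = np.zeros(10, dtype=bool)
        s[:5] = True
        p = SsgseaParams(alpha=0.0)
        assert enrichment_score(ranks, s, p) == pytest.approx(
            -enrichment_score(ranks, ~s, p), abs=1e-12
        )


def random_problem(rng, n_genes, n_cells, n_sets, integer=False):
    if integer:
        X = rng.integers(0, 5, size=(n_genes, n_cells)).astype(float)
    else:
        X = rng.gamma(1.0, 2.0, size=(n_genes, n_cells))
    sets = []
    for k in range(n_sets):
        size = rng.integers(1, max(2, n_genes // 2))
        sets.append(sorted(rng.choice(n_genes, size=size, replace=False).tolist()))
    return X, sets


def scorer_scores(X, set_indices, alpha=0.25, tie_method="average"):
    genes = [f"g{i}" for i in range(X.shape[0])]
    sets = [GeneSet(f"s{k}", [genes[i] for i in idx]) for k, idx in enumerate(set_indices)]
    sc = SsgseaScorer(gene_sets=sets, gene_names=genes, alpha=alpha, tie_method=tie_method)
    return sc.fit(X.T).transform(X.T)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("integer", [False, True], ids=["continuous", "tied-integers"])
    def test_score_matrix_matches_positional_loop(self, seed, integer):
        rng = np.random.default_rng(seed)
        X, sets = random_problem(rng, n_genes=25, n_cells=8, n_sets=3, integer=integer)
        got = scorer_scores(X, sets)
        want = np.asarray(oracle_score_matrix(X.tolist(), sets))
        np.testing.assert_allclose(got, want, atol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_genes=st.integers(5, 50),
        n_cells=st.integers(1, 20),
        alpha=st.sampled_from([0.0, 0.25, 1.0]),
        tie_method=st.sampled_from(["average", "ordinal"]),
        integer=st.booleans(),
    )
    def test_property_oracle_equivalence(self, seed, n_genes, n_cells, alpha, tie_method, integer):
        rng = np.random.default_rng(seed)
        X, sets = random_problem(rng, n_genes, n_cells, n_sets=2, integer=integer)
        got = scorer_scores(X, sets, alpha=alpha, tie_method=tie_method)
        want = np.asarray(oracle_score_matrix(X.tolist(), sets, alpha, tie_method))
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestScoreMatrix:
    def test_single_cell_batch_consistency(self, small_matrix):
        sets = [GeneSet("S", ["g1", "g3"]), GeneSet("R", ["g2"])]
        full = score_matrix(small_matrix, sets)
        one = score_matrix(small_matrix.subset_cells(["c2"]), sets)
        np.testing.assert_allclose(full.scores[1], one.scores[0], atol=1e-12)

    def test_duplicate_cells_get_identical_rows(self):
        from immunanno import ExpressionMatrix

        m = ExpressionMatrix(
            ["g1", "g2", "g3"], ["a", "b"], np.array([[5.0, 5.0], [2.0, 2.0], [7.0, 7.0]])
        )
        t = score_matrix(m, [GeneSet("S", ["g1"])])
        assert t.scores[0] == pytest.approx(t.scores[1])

    def test_monotone_transform_invariance(self, rng):
        # log1p and positive scaling preserve within-cell ranks, hence scores
        from immunanno import ExpressionMatrix

        X = rng.integers(0, 6, size=(30, 10)).astype(float)
        genes = [f"g{i}" for i in range(30)]
        cells = [f"c{i}" for i in range(10)]
        sets = [GeneSet("S", genes[:7]), GeneSet("R", genes[7:15])]
        base = score_matrix(ExpressionMatrix(genes, cells, X), sets).scores
        logd = score_matrix(ExpressionMatrix(genes, cells, np.log1p(X)), sets).scores
        scaled = score_matrix(ExpressionMatrix(genes, cells, X * 3.7), sets).scores
        np.testing.assert_allclose(base, logd, atol=1e-12)
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_normalize_scores_preserves_argmax(self, rng):
        from immunanno import ExpressionMatrix

        X = rng.gamma(1.0, 1.0, size=(40, 15))
        genes = [f"g{i}" for i in range(40)]
        m = ExpressionMatrix(genes, [f"c{i}" for i in range(15)], X)
        sets = [GeneSet(f"s{k}", genes[k * 8 : (k + 1) * 8]) for k in range(4)]
        raw = score_matrix(m, sets, SsgseaParams(normalize_scores=False)).scores
        norm = score_matrix(m, sets, SsgseaParams(normalize_scores=True)).scores
        np.testing.assert_array_equal(raw.argmax(axis=1), norm.argmax(axis=1))
        assert norm.max() - norm.min() <= 1.0 + 1e-12

    def test_zero_overlap_set_excluded_with_warning(self, small_matrix):
        sets = [GeneSet("S", ["g1"]), GeneSet("ghost", ["zz"])]
        with pytest.warns(UserWarning, match="ghost"):
            t = score_matrix(small_matrix, sets)
        assert t.set_names == ["S"]
        assert t.excluded_sets[0][0] == "ghost"

    def test_all_sets_excluded_raises(self, small_matrix):
        with pytest.raises(ScoringError):
            with pytest.warns(UserWarning):
                score_matrix(small_matrix, [GeneSet("ghost", ["zz"])])


class TestSklearnContract:
    def test_clone_and_feature_names(self, small_matrix):
        sets = [GeneSet("S", ["g1", "g3"]), GeneSet("R", ["g2", "g4"])]
        sc = SsgseaScorer(gene_sets=sets, gene_names=small_matrix.gene_ids, alpha=0.5)
        sc2 = clone(sc)
        assert sc2.get_params()["alpha"] == 0.5
        sc2.fit(small_matrix.cells_by_genes())
        assert list(sc2.get_feature_names_out()) == ["S", "R"]

    def test_dataframe_input_provides_gene_names(self, small_matrix):
        import pandas as pd

        df = pd.DataFrame(small_matrix.cells_by_genes(), columns=small_matrix.gene_ids)
        sc = SsgseaScorer(gene_sets=[GeneSet("S", ["g1"])]).fit(df)
        assert sc.gene_names_ == small_matrix.gene_ids

    def test_invalid_params_rejected(self):
        with pytest.raises(InputError):
            SsgseaParams(alpha=-1)
        with pytest.raises(InputError):
            SsgseaParams(tie_method="dense")
        with pytest.raises(InputError):
            SsgseaParams(min_genes_present=0)
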