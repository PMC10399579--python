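"""Per-cell single-sample GSEA (ssGSEA) enrichment scoring.

Each cell is treated as one sample.  Genes are ranked within the cell
(largest expression -> rank N) and, walking the genes from highest to
lowest rank, the score for a gene set S is the summed difference between
the rank-weighted in-set ECDF and the uniform out-of-set ECDF::

    P_in(i)  = sum_{g in S, pos(g) <= i} r_g^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{g not in S, pos(g) <= i}| / (N - |S|)
    ES(S)    = sum_{i=1..N} (P_in(i) - P_out(i))

with the published ssGSEA rank-weight exponent ``alpha = 0.25`` as default.
Tied expression values share their rank under ``tie_method="average"``; the
walk order among tied genes is fixed as ascending gene index so results are
deterministic.  Because only within-cell ranks enter the statistic, any
strictly increasing per-cell transform (log1p, library-size scaling) leaves
every score — and therefore every annotation — unchanged.

The implementation below evaluates the equivalent closed form

    ES(S) = sum_{g in S} w_g A_g / sum_{g in S} w_g
            - (N(N+1)/2 - sum_{g in S} A_g) / (N - |S|)

where ``w_g = r_g^alpha`` and ``A_g = N - pos(g) + 1`` counts the positions
at which gene g has already been passed; this turns the per-set walk into
two matrix products over all cells and sets at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import InputError, ScoringError
from .genesets import GeneSet
from .matrix_io import ExpressionMatrix


@dataclass
class SsgseaParams:
    """Tunable constants of the enrichment statistic.

    alpha
        Rank-weight exponent (>= 0).  0.25 is the published ssGSEA default;
        0 weighs all in-set genes equally (classic KS-style walk).
    tie_method
        "average" (tied values share the mean rank) or "ordinal"
        (ties broken by ascending gene index).
    normalize_scores
        Divide all scores by the global (max - min) range.  Cosmetic: a
        positive global scaling can never change a per-cell argmax.
    min_genes_present
        Sets with fewer genes present in the matrix are dropped from
        scoring; below 3 a warning is emitted since tiny overlaps make the
        statistic noisy.
    """

    alpha: float = 0.25
    tie_method: str = "average"
    normalize_scores: bool = False
    min_genes_present: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InputError("alpha must be >= 0")
        if self.tie_method not in ("average", "ordinal"):
            raise InputError(f"unknown tie_method {self.tie_method!r}")
        if self.min_genes_present < 1:
            raise InputError("min_genes_present must be >= 1")


@dataclass
class EnrichmentScoreTable:
    """cells x gene-sets matrix of enrichment scores for one scoring round."""

    cell_barcodes: list
    set_names: list
    scores: np.ndarray
    excluded_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_barcodes), len(self.set_names)):
            raise InputError("score matrix shape inconsistent with labels")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise InputError("enrichment scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_barcodes, columns=self.set_names)


def rank_genes(cell_expression: Sequence, tie_method: str = "average") -> np.ndarray:
    """Within-cell ranks in 1..N, largest value -> rank N."""
    x = np.asarray(cell_expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("need a 1-d expression vector of at least 2 genes")
    if tie_method not in ("average", "ordinal"):
        raise InputError(f"unknown tie_method {tie_method!r}")
    return scipy.stats.rankdata(x, method=tie_method)


def _walk_positions(ranks: np.ndarray) -> np.ndarray:
    """1-based walk position per gene: decreasing rank, ties by ascending index."""
    order = np.argsort(-ranks, axis=-1, kind="stable")
    pos = np.empty_like(ranks)
    n = ranks.shape[-1]
    np.put_along_axis(
        pos, order, np.broadcast_to(np.arange(1, n + 1, dtype=float), ranks.shape), axis=-1
    )
    return pos


def enrichment_score(
    ranks: Sequence,
    set_membership: Sequence,
    params: SsgseaParams = None,
) -> float:
    """ES for one cell and one gene set.

    ``set_membership`` is either a boolean mask over the genes or an array
    of member gene indices.  Requires 0 < |S| < N.
    """
    params = params or SsgseaParams()
    r = np.asarray(ranks, dtype=float)
    n = r.size
    member = np.zeros(n, dtype=bool)
    sm = np.asarray(set_membership)
    if sm.dtype == bool:
        if sm.size != n:
            raise InputError("membership mask length must match ranks")
        member = sm
    else:
        member[sm.astype(int)] = True
    size = int(member.sum())
    if size == 0:
        raise ScoringError("gene set has no genes in the matrix")
    if size == n:
        raise InputError("gene set covers every gene; out-of-set ECDF undefined")
    pos = _walk_positions(r)
    a = n - pos + 1
    w = r**params.alpha
    w_in = w[member].sum()
    es = (w[member] * a[member]).sum() / w_in
    es -= (n * (n + 1) / 2 - a[member].sum()) / (n - size)
    return float(es)


class SsgseaScorer(BaseEstimator, TransformerMixin):
    """Transform cells x genes expression into cells x gene-sets ssGSEA scores.

    scikit-learn transformer: ``fit`` binds the gene sets to the matrix's
    gene universe (intersecting away absent genes, dropping sets with fewer
    than ``min_genes_present`` overlapping genes), ``transform`` computes
    one enrichment score per cell and surviving set.

    Parameters
    ----------
    gene_sets : sequence of GeneSet
    gene_names : sequence of str, optional
        Column names of X.  May be omitted when X is a DataFrame.
    alpha, tie_method, normalize_scores, min_genes_present
        See :class:`SsgseaParams`.

    Attributes
    ----------
    sets_used_ : list of GeneSet restricted to genes present in X
    excluded_sets_ : list of (name, reason) for sets dropped at fit time
    member_mask_ : (n_sets_used, n_genes) boolean membership matrix
    """

    def __init__(
        self,
        gene_sets: Sequence = None,
        gene_names: Sequence = None,
        alpha: float = 0.25,
        tie_method: str = "average",
        normalize_scores: bool = False,
        min_genes_present: int = 1,
    ) -> None:
        self.gene_sets = gene_sets
        self.gene_names = gene_names
        self.alpha = alpha
        self.tie_method = tie_method
        self.normalize_scores = normalize_scores
        self.min_genes_present = min_genes_present

    # -- helpers --------------------------------------------------------
    def _params(self) -> SsgseaParams:
        return SsgseaParams(
            alpha=self.alpha,
            tie_method=self.tie_method,
            normalize_scores=self.normalize_scores,
            min_genes_present=self.min_genes_present,
        )

    def _resolve_gene_names(self, X) -> list:
        if self.gene_names is not None:
            return [str(g) for g in self.gene_names]
        if hasattr(X, "columns"):
            return [str(g) for g in X.columns]
        raise InputError("gene_names required unless X is a DataFrame")

    def fit(self, X, y=None):
        params = self._params()  # validates constants
        if not self.gene_sets:
            raise InputError("gene_sets must be a non-empty sequence of GeneSet")
        genes = self._resolve_gene_names(X)
        Xv = check_array(X, accept_sparse=False, dtype=float, ensure_min_features=2)
        if Xv.shape[1] != len(genes):
            raise InputError(
                f"X has {Xv.shape[1]} gene columns but {len(genes)} gene names given"
            )
        n = len(genes)
        index = {g: i for i, g in enumerate(genes)}
        self.sets_used_: List[GeneSet] = []
        self.excluded_sets_: List[Tuple[str, str]] = []
        rows = []
        for s in self.gene_sets:
            idx = [index[g] for g in s.genes if g in index]
            if len(idx) < params.min_genes_present or len(idx) == 0:
                self.excluded_sets_.append(
                    (s.name, f"{len(idx)} of {len(s.genes)} genes present")
                )
                warnings.warn(
                    f"gene set {s.name!r} excluded from scoring: only "
                    f"{len(idx)} of its {len(s.genes)} genes are in the matrix",
                    stacklevel=2,
                )
                continue
            if len(idx) == n:
                raise InputError(
                    f"gene set {s.name!r} covers every gene in the matrix"
                )
            if len(idx) < len(s.genes):
                warnings.warn(
                    f"gene set {s.name!r}: {len(s.genes) - len(idx)} genes "
                    "absent from the matrix were ignored",
                    stacklevel=2,
                )
            if len(idx) < 3:
                warnings.warn(
                    f"gene set {s.name!r} is scored on only {len(idx)} genes; "
                    "scores from fewer than 3 genes are unstable",
                    stacklevel=2,
                )
            self.sets_used_.append(GeneSet(s.name, [genes[i] for i in idx]))
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            rows.append(mask)
        if not self.sets_used_:
            raise ScoringError("no gene set overlaps the matrix's genes")
        self.member_mask_ = np.vstack(rows)
        self.gene_names_ = genes
        self.n_features_in_ = n
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "member_mask_")
        params = self._params()
        Xv = check_array(X, accept_sparse=False, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise InputError(
                f"X has {Xv.shape[1]} genes; scorer was fitted with {self.n_features_in_}"
            )
        n = self.n_features_in_
        M = self.member_mask_.astype(float)  # sets x genes
        sizes = M.sum(axis=1)
        total_a = n * (n + 1) / 2
        out = np.empty((Xv.shape[0], M.shape[0]))
        # chunk cells to bound the dense rank/position workspace
        step = max(1, int(4e6 // max(n, 1)))
        for lo in range(0, Xv.shape[0], step):
            block = Xv[lo : lo + step]
            ranks = scipy.stats.rankdata(block, method=params.tie_method, axis=1)
            pos = _walk_positions(ranks)
            a = n - pos + 1
            w = ranks**params.alpha
            w_in = w @ M.T
            num_in = (w * a) @ M.T
            a_in = a @ M.T
            out[lo : lo + step] = num_in / w_in - (total_a - a_in) / (n - sizes)
        if params.normalize_scores:
            rng = out.max() - out.min()
            if rng > 0:
                out = out / rng
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "member_mask_")
        return np.asarray([s.name for s in self.sets_used_], dtype=object)


def score_matrix(
    m: ExpressionMatrix,
    sets: Sequence,
    params: SsgseaParams = None,
) -> EnrichmentScoreTable:
    """Score every cell of ``m`` against every gene set.

    Cells are scored independently; sets without any gene in the matrix are
    excluded with a warning and recorded in ``excluded_sets``.
    """
    params = params or SsgseaParams()
    scorer = SsgseaScorer(
        gene_sets=list(sets),
        gene_names=m.gene_ids,
        alpha=params.alpha,
        tie_method=params.tie_method,
        normalize_scores=params.normalize_scores,
        min_genes_present=params.min_genes_present,
    )
    X = m.cells_by_genes()
    scores = scorer.fit(X).transform(X)
    return EnrichmentScoreTable(
        cell_barcodes=list(m.cell_barcodes),
        set_names=[s.name for s in scorer.sets_used_],
        scores=scores,
        excluded_sets=list(scorer.excluded_sets_),
    )
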