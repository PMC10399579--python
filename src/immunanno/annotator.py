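"""Layer-by-layer immune cell type assignment.

Cells are first (optionally) pre-screened as immune vs non-immune, then
labelled at the major-type layer by the largest enrichment score among the
nine layer-1 sets, and each labelled group is re-scored among only the
children of its winning type (T cells among {CD4 T, CD8 T}, those among the
CD4/CD8 subtypes, and so on).  Restricting each decision to siblings keeps
transcriptionally similar but distantly related types (e.g. NK vs CD8 T)
from competing directly, which is the point of the hierarchical scheme.

Scores are per-cell quantities, so annotating any subset of cells yields
the same labels as annotating the full matrix.  Cells whose expression
vector is all zero carry no ranking information and are labelled
"unassigned".  Ties at an argmax are broken deterministically in favour of
the earlier set in the hierarchy's declared order, with margin 0 recorded
so downstream users can filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ConfigError, InputError
from .genesets import SignatureHierarchy, load_canonical_hierarchy
from .matrix_io import ANNOTATION_COLUMNS, ExpressionMatrix
from .ssgsea import SsgseaParams, SsgseaScorer

IMMUNE = "immune"
NON_IMMUNE = "non_immune"
UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    """Per-cell labels, winning scores and runner-up margins for layers 1-3.

    Backed by a DataFrame with one row per cell and columns ``barcode``,
    ``prescreen_label`` and ``layer{k}_label/score/margin`` for k = 1..3.
    Labels of layers a cell never reached are ``None``; a cell labelled at
    layer k always carries labels at all shallower layers, each a child of
    the previous one.
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def labels(self, layer: int) -> pd.Series:
        return self.frame.set_index("barcode")[f"layer{layer}_label"]

    def deepest_labels(self) -> pd.Series:
        """The most specific label per cell (prescreen label if no layer 1)."""
        out = self.frame["prescreen_label"].copy()
        for k in (1, 2, 3):
            col = self.frame[f"layer{k}_label"]
            out = col.where(col.notna(), out)
        out.index = self.frame["barcode"]
        return out

    def check_consistency(self, hierarchy: SignatureHierarchy) -> None:
        """Raise if any cell's label path violates the hierarchy."""
        for _, row in self.frame.iterrows():
            if row["prescreen_label"] in (NON_IMMUNE, UNASSIGNED):
                if any(row[f"layer{k}_label"] is not None for k in (1, 2, 3)):
                    raise ConfigError(
                        f"cell {row['barcode']}: {row['prescreen_label']} but has layer labels"
                    )
                continue
            prev = None
            for k in (1, 2, 3):
                lab = row[f"layer{k}_label"]
                if lab is None:
                    if any(row[f"layer{j}_label"] is not None for j in range(k + 1, 4)):
                        raise ConfigError(
                            f"cell {row['barcode']}: layer {k} empty but deeper label set"
                        )
                    break
                if k == 1:
                    if lab not in [n.label for n in hierarchy.roots]:
                        raise ConfigError(f"cell {row['barcode']}: {lab!r} is not a root type")
                else:
                    kids = [c.label for c in hierarchy.node(prev).children]
                    if lab not in kids:
                        raise ConfigError(
                            f"cell {row['barcode']}: {lab!r} is not a subtype of {prev!r}"
                        )
                prev = lab


def _empty_frame(barcodes: Sequence) -> pd.DataFrame:
    df = pd.DataFrame({"barcode": list(barcodes)})
    df["prescreen_label"] = None
    for k in (1, 2, 3):
        df[f"layer{k}_label"] = None
        df[f"layer{k}_score"] = np.nan
        df[f"layer{k}_margin"] = np.nan
    return df


class HierarchicalAnnotator(BaseEstimator, ClassifierMixin):
    """scikit-learn style classifier annotating cells down a marker hierarchy.

    The "training" is knowledge-based: ``fit`` binds the signature
    hierarchy to the matrix's gene universe and validates that every
    competing set is scorable; ``predict`` returns the deepest label per
    cell.  Use :meth:`annotate` for the full per-layer result.

    Parameters
    ----------
    hierarchy : SignatureHierarchy, optional
        Defaults to the bundled canonical immune taxonomy with its
        illustrative marker sets.
    gene_names : sequence of str, optional
        Gene (column) names of X; may be omitted when X is a DataFrame.
    prescreen : bool
        Run the immune / non-immune decision first (default).  Disable for
        datasets from which non-immune cells were already removed.
    max_layer : int in {1, 2, 3}
        Deepest layer to annotate.
    alpha, tie_method, min_genes_present
        Enrichment-statistic constants, see :class:`SsgseaParams`.
    min_margin : float, optional
        Optional extension (off by default): a decision whose margin over
        the runner-up falls below this value is withheld, leaving the cell
        at its parent label.

    Attributes
    ----------
    hierarchy_ : the resolved SignatureHierarchy
    gene_names_ : gene universe the annotator was fitted to
    classes_ : all labels the annotator can emit
    """

    def __init__(
        self,
        hierarchy: SignatureHierarchy = None,
        gene_names: Sequence = None,
        prescreen: bool = True,
        max_layer: int = 3,
        alpha: float = 0.25,
        tie_method: str = "average",
        min_genes_present: int = 1,
        min_margin: Optional[float] = None,
    ) -> None:
        self.hierarchy = hierarchy
        self.gene_names = gene_names
        self.prescreen = prescreen
        self.max_layer = max_layer
        self.alpha = alpha
        self.tie_method = tie_method
        self.min_genes_present = min_genes_present
        self.min_margin = min_margin

    def _scorer(self, sets) -> SsgseaScorer:
        return SsgseaScorer(
            gene_sets=list(sets),
            gene_names=self.gene_names_,
            alpha=self.alpha,
            tie_method=self.tie_method,
            min_genes_present=self.min_genes_present,
        )

    def fit(self, X, y=None):
        if self.max_layer not in (1, 2, 3):
            raise InputError("max_layer must be 1, 2 or 3")
        SsgseaParams(alpha=self.alpha, tie_method=self.tie_method)  # validate
        self.hierarchy_ = self.hierarchy if self.hierarchy is not None else load_canonical_hierarchy()
        if self.gene_names is not None:
            self.gene_names_ = [str(g) for g in self.gene_names]
        elif hasattr(X, "columns"):
            self.gene_names_ = [str(g) for g in X.columns]
        else:
            raise InputError("gene_names required unless X is a DataFrame")
        Xv = check_array(X, dtype=float, ensure_min_features=2)
        if Xv.shape[1] != len(self.gene_names_):
            raise InputError(
                f"X has {Xv.shape[1]} gene columns but {len(self.gene_names_)} names given"
            )
        if self.prescreen:
            if self.hierarchy_.prescreen is None:
                raise ConfigError(
                    "prescreen requested but the hierarchy has no immune/"
                    "non-immune pre-screen pair (pass prescreen=False to skip)"
                )
            # pre-screen sets must be scorable: failing that is a config error
            universe = set(self.gene_names_)
            for s in self.hierarchy_.prescreen:
                if not any(g in universe for g in s.genes):
                    raise ConfigError(
                        f"pre-screen set {s.name!r} shares no genes with the matrix"
                    )
        self.n_features_in_ = Xv.shape[1]
        labels = [UNASSIGNED, NON_IMMUNE, IMMUNE] + self.hierarchy_.labels()
        self.classes_ = np.asarray(labels, dtype=object)
        return self

    # -- core -----------------------------------------------------------
    def annotate(self, X, barcodes: Sequence = None) -> AnnotationResult:
        """Full per-layer annotation of the cells (rows) of X."""
        check_is_fitted(self, "hierarchy_")
        Xv = check_array(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise InputError(
                f"X has {Xv.shape[1]} genes; annotator was fitted with {self.n_features_in_}"
            )
        if barcodes is None:
            barcodes = (
                [str(b) for b in X.index] if hasattr(X, "index") else
                [f"cell{i}" for i in range(Xv.shape[0])]
            )
        if len(barcodes) != Xv.shape[0]:
            raise InputError("barcodes length must match the number of cells")
        df = _empty_frame(barcodes)

        nonzero = np.flatnonzero(Xv.any(axis=1))
        df.loc[df.index.difference(nonzero), "prescreen_label"] = UNASSIGNED

        # pre-screen: argmax over the immune / non-immune pair
        if self.prescreen:
            imm_set, non_set = self.hierarchy_.prescreen
            if nonzero.size:
                scorer = self._scorer([imm_set, non_set]).fit(Xv[nonzero])
                if len(scorer.sets_used_) < 2:
                    raise ConfigError(
                        "a pre-screen set became unscorable; pre-screening "
                        "cannot be skipped silently (use prescreen=False)"
                    )
                s = scorer.transform(Xv[nonzero])
                is_immune = s[:, 0] >= s[:, 1]
                df.loc[nonzero[is_immune], "prescreen_label"] = IMMUNE
                df.loc[nonzero[~is_immune], "prescreen_label"] = NON_IMMUNE
            eligible = nonzero[
                (df.loc[nonzero, "prescreen_label"] == IMMUNE).to_numpy()
            ]
        else:
            eligible = nonzero

        if eligible.size == 0:
            warnings.warn("no cells eligible for annotation (empty immune partition)")
            return AnnotationResult(df)

        # layer 1: sibling competition among the root (major) types
        groups = {None: eligible}
        for layer in range(1, self.max_layer + 1):
            next_groups: dict = {}
            for parent, cells in groups.items():
                if cells.size == 0:
                    continue
                siblings = (
                    self.hierarchy_.roots if parent is None
                    else self.hierarchy_.node(parent).children
                )
                if not siblings:
                    continue  # leaf type: stop deepening
                res = self._decide(Xv, cells, [n.gene_set for n in siblings])
                if res is None:
                    continue
                lab_idx, score, margin = res
                names = [n.label for n in siblings]
                if self.min_margin is not None:
                    keep = margin >= self.min_margin
                else:
                    keep = np.ones(cells.size, dtype=bool)
                kept = cells[keep]
                df.loc[kept, f"layer{layer}_label"] = [names[i] for i in lab_idx[keep]]
                df.loc[kept, f"layer{layer}_score"] = score[keep]
                df.loc[kept, f"layer{layer}_margin"] = margin[keep]
                for i, name in enumerate(names):
                    next_groups[name] = kept[lab_idx[keep] == i]
            groups = next_groups
            if not groups:
                break
        return AnnotationResult(df)

    def _decide(self, Xv, cells, sets):
        """Argmax competition of ``cells`` among ``sets``; None if skipped."""
        if len(sets) >= 2:
            scorer = self._scorer(sets).fit(Xv[cells])
            if len(scorer.sets_used_) < 2:
                warnings.warn(
                    f"fewer than 2 scorable sets among {[s.name for s in sets]}; "
                    "layer skipped for these cells"
                )
                return None
            s = scorer.transform(Xv[cells])
            # reorder columns back to declared order for deterministic ties
            lab_idx = np.argmax(s, axis=1)
            order = np.argsort(-s, axis=1, kind="stable")
            win = s[np.arange(s.shape[0]), order[:, 0]]
            second = s[np.arange(s.shape[0]), order[:, 1]]
            used_names = [g.name for g in scorer.sets_used_]
            declared = [g.name for g in sets]
            remap = np.asarray([declared.index(n) for n in used_names])
            return remap[lab_idx], win, win - second
        # degenerate single-candidate layer: assign directly
        scorer = self._scorer(sets).fit(Xv[cells])
        s = scorer.transform(Xv[cells])
        return (
            np.zeros(cells.size, dtype=int),
            s[:, 0],
            np.full(cells.size, np.nan),
        )

    def predict(self, X) -> np.ndarray:
        """Deepest label per cell (prescreen outcome for unannotated cells)."""
        return self.annotate(X).deepest_labels().to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# functional wrappers over the estimator


def prescreen_immune(
    m: ExpressionMatrix,
    hierarchy: SignatureHierarchy,
    params: SsgseaParams = None,
) -> pd.Series:
    """Immune / non-immune / unassigned call per cell (barcode-indexed)."""
    params = params or SsgseaParams()
    ann = HierarchicalAnnotator(
        hierarchy=hierarchy,
        gene_names=m.gene_ids,
        prescreen=True,
        max_layer=1,
        alpha=params.alpha,
        tie_method=params.tie_method,
        min_genes_present=params.min_genes_present,
    )
    X = m.cells_by_genes()
    res = ann.fit(X).annotate(X, barcodes=m.cell_barcodes)
    return res.frame.set_index("barcode")["prescreen_label"]


def annotate_layer(
    m: ExpressionMatrix,
    sibling_sets: Sequence,
    cell_subset: Sequence,
    params: SsgseaParams = None,
) -> pd.DataFrame:
    """One sibling competition: label/score/margin for the listed cells."""
    params = params or SsgseaParams()
    if len(sibling_sets) < 2:
        raise InputError("need at least 2 sibling gene sets")
    if len(cell_subset) == 0:
        raise InputError("cell_subset must be non-empty")
    sub = m.subset_cells(cell_subset)
    ann = HierarchicalAnnotator(
        gene_names=m.gene_ids,
        prescreen=False,
        alpha=params.alpha,
        tie_method=params.tie_method,
        min_genes_present=params.min_genes_present,
    )
    ann.gene_names_ = [str(g) for g in m.gene_ids]  # bypass full fit: one layer only
    ann.n_features_in_ = m.n_genes
    Xv = sub.cells_by_genes()
    res = ann._decide(Xv, np.arange(Xv.shape[0]), list(sibling_sets))
    if res is None:
        return pd.DataFrame(columns=["barcode", "label", "score", "margin"])
    lab_idx, score, margin = res
    names = [s.name for s in sibling_sets]
    return pd.DataFrame(
        {
            "barcode": sub.cell_barcodes,
            "label": [names[i] for i in lab_idx],
            "score": score,
            "margin": margin,
        }
    )


def annotate_hierarchical(
    m: ExpressionMatrix,
    hierarchy: SignatureHierarchy,
    params: SsgseaParams = None,
    *,
    prescreen: bool = True,
    max_layer: int = 3,
    min_margin: Optional[float] = None,
) -> AnnotationResult:
    """Annotate every cell of ``m`` down the hierarchy (the main entry point)."""
    params = params or SsgseaParams()
    ann = HierarchicalAnnotator(
        hierarchy=hierarchy,
        gene_names=m.gene_ids,
        prescreen=prescreen,
        max_layer=max_layer,
        alpha=params.alpha,
        tie_method=params.tie_method,
        min_genes_present=params.min_genes_present,
        min_margin=min_margin,
    )
    X = m.cells_by_genes()
    return ann.fit(X).annotate(X, barcodes=m.cell_barcodes)
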