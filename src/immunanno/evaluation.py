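"""Benchmarking annotations against ground-truth labels.

Covers the three ingredients of the evaluation protocol: harmonizing
heterogeneous author labels onto the package taxonomy (with an explicit
DISCARD sentinel for ambiguous labels such as doublet calls), stratified
subsampling of unbalanced datasets (a tiered rule for very large types and
a flat per-type cap for tool benchmarks), and standard confusion-matrix
metrics (overall/micro accuracy, per-class precision/recall/F1, macro
averages).  Metric arithmetic is delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .errors import InputError
from .genesets import SignatureHierarchy
from .matrix_io import ExpressionMatrix
from .ssgsea import SsgseaParams

#: sentinel in a LabelMap marking truth labels to exclude from evaluation
DISCARD = "DISCARD"


@dataclass
class LabelMap:
    """Mapping original truth labels -> standardized labels (or DISCARD).

    The map must be total over the labels it is applied to; an unmapped
    label is an error so silent label leakage cannot happen.
    """

    mapping: Mapping

    @classmethod
    def identity(cls, labels: Sequence) -> "LabelMap":
        return cls({l: l for l in labels})

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "LabelMap":
        """Two-column CSV (original, standardized); DISCARD keyword honoured."""
        df = pd.read_csv(path, header=0)
        if df.shape[1] < 2:
            raise InputError(f"label map {path} needs two columns")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def harmonize_labels(
    truth: Sequence, label_map: Union[LabelMap, Mapping]
) -> Tuple[np.ndarray, np.ndarray]:
    """Standardize truth labels; returns (standardized, discard_mask).

    Discarded cells keep a placeholder in the standardized array but are
    flagged in the mask; unmapped labels raise, listing the offenders.
    """
    mapping = label_map.mapping if isinstance(label_map, LabelMap) else label_map
    truth = np.asarray([str(t) for t in truth], dtype=object)
    unmapped = sorted({t for t in truth if t not in mapping})
    if unmapped:
        raise InputError(f"truth labels without a mapping: {unmapped}")
    std = np.asarray([mapping[t] for t in truth], dtype=object)
    discard = std == DISCARD
    return std, discard


def stratified_subsample(
    truth_labels: Sequence,
    mode: str = "tiered",
    cap: int = 3000,
    seed: int = 0,
) -> np.ndarray:
    """Per-type subsampling indices (sorted), uniform without replacement.

    mode "tiered": types with more than 50,000 cells are cut to 12,000;
    20,000-50,000 to 8,000; smaller types (including the 10,000-20,000
    band) are kept whole.  mode "capped": every type is cut to at most
    ``cap`` cells (the benchmark protocol's 3,000-cap).  Reproducible under
    ``seed``.
    """
    labels = np.asarray([str(t) for t in truth_labels], dtype=object)
    if labels.size == 0:
        raise InputError("truth_labels must be non-empty")
    if mode not in ("tiered", "capped"):
        raise InputError(f"unknown mode {mode!r}")
    if mode == "capped" and cap <= 0:
        raise InputError("cap must be positive")
    rng = np.random.default_rng(seed)
    keep = []
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n = idx.size
        if mode == "tiered":
            quota = 12000 if n > 50000 else 8000 if n > 20000 else n
        else:
            quota = min(n, cap)
        if quota < n:
            idx = rng.choice(idx, size=quota, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics for one annotation round.

    ``confusion`` rows are truth classes, columns predicted classes (the
    union vocabulary); ``accuracy`` is micro (cell-weighted) accuracy;
    ``per_class`` holds precision/recall/F1/support per truth class with
    classes absent on one side scored 0 where undefined.
    """

    confusion: pd.DataFrame
    accuracy: float
    per_class: pd.DataFrame
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_accuracy: float  # mean per-class recall, the macro "accuracy"
    n_cells: int
    n_discarded: int = 0

    def to_frame(self) -> pd.DataFrame:
        summary = pd.DataFrame(
            {
                "metric": [
                    "accuracy",
                    "macro_accuracy",
                    "macro_precision",
                    "macro_recall",
                    "macro_f1",
                    "n_cells",
                    "n_discarded",
                ],
                "value": [
                    self.accuracy,
                    self.macro_accuracy,
                    self.macro_precision,
                    self.macro_recall,
                    self.macro_f1,
                    self.n_cells,
                    self.n_discarded,
                ],
            }
        )
        return summary


def evaluate(
    pred: Sequence, truth: Sequence, n_discarded: int = 0
) -> EvaluationReport:
    """Confusion matrix + accuracy/precision/recall/F1 of predictions vs truth."""
    pred = np.asarray([str(p) for p in pred], dtype=object)
    truth = np.asarray([str(t) for t in truth], dtype=object)
    if pred.size != truth.size:
        raise InputError(f"{pred.size} predictions vs {truth.size} truth labels")
    if pred.size == 0:
        raise InputError("nothing to evaluate")
    classes = sorted(set(truth) | set(pred))
    cm = _sk_confusion(truth, pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=classes,
    )
    observed = per_class["support"] > 0  # macro averages over truth classes only
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(per_class.loc[observed, "precision"].mean()),
        macro_recall=float(per_class.loc[observed, "recall"].mean()),
        macro_f1=float(per_class.loc[observed, "f1"].mean()),
        macro_accuracy=float(per_class.loc[observed, "recall"].mean()),
        n_cells=int(cm.sum()),
        n_discarded=n_discarded,
    )


def evaluate_layers(
    annotation: pd.DataFrame, truth: pd.DataFrame, max_layer: int = 3
) -> dict:
    """Per-layer reports; layer-k metrics use only cells whose truth has a
    label at that layer."""
    reports = {}
    ann = annotation.set_index("barcode")
    tr = truth.set_index("barcode") if "barcode" in truth.columns else truth
    common = ann.index.intersection(tr.index)
    if len(common) == 0:
        raise InputError("annotation and truth share no barcodes")
    for k in range(1, max_layer + 1):
        col = f"layer{k}_label" if f"layer{k}_label" in tr.columns else f"layer{k}"
        if col not in tr.columns:
            continue
        t = tr.loc[common, col]
        mask = t.notna() & (t != "")
        if mask.sum() == 0:
            continue
        p = ann.loc[common, f"layer{k}_label"][mask]
        p = p.where(p.notna(), UNLABELLED)
        reports[k] = evaluate(p, t[mask])
    return reports


UNLABELLED = "(unlabelled)"


def mean_report(reports: Sequence) -> EvaluationReport:
    """Arithmetic mean of metrics over replicate reports (class-aligned)."""
    if not reports:
        raise InputError("no reports to average")
    classes = sorted(set().union(*[set(r.per_class.index) for r in reports]))
    conf = sum(
        r.confusion.reindex(index=classes, columns=classes, fill_value=0)
        for r in reports
    ) / len(reports)
    per_class = (
        sum(
            r.per_class.reindex(index=classes, fill_value=0.0) for r in reports
        )
        / len(reports)
    )
    return EvaluationReport(
        confusion=conf,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        per_class=per_class,
        macro_precision=float(np.mean([r.macro_precision for r in reports])),
        macro_recall=float(np.mean([r.macro_recall for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        macro_accuracy=float(np.mean([r.macro_accuracy for r in reports])),
        n_cells=int(np.mean([r.n_cells for r in reports])),
        n_discarded=int(np.mean([r.n_discarded for r in reports])),
    )


def replicate_benchmark(
    m: ExpressionMatrix,
    hierarchy: SignatureHierarchy,
    truth: pd.DataFrame,
    reps: int = 5,
    cap: int = 3000,
    seeds: Optional[Sequence] = None,
    layer: int = 1,
    params: SsgseaParams = None,
    prescreen: bool = False,
) -> Tuple[list, EvaluationReport]:
    """Subsample -> annotate -> evaluate, replicated, plus the mean report.

    Five replicates with a 3,000-cells-per-type cap is the benchmark
    protocol default; the final numbers are the arithmetic mean over
    replicates.  ``truth`` needs a ``barcode`` column (or index) and a
    ``layer{k}`` (or ``layer{k}_label``) column for the evaluated layer.
    """
    from .annotator import annotate_hierarchical  # local: avoid import cycle

    if reps < 1:
        raise InputError("reps must be >= 1")
    seeds = list(seeds) if seeds is not None else list(range(reps))
    if len(seeds) != reps:
        raise InputError(f"need {reps} seeds, got {len(seeds)}")
    tr = truth.set_index("barcode") if "barcode" in truth.columns else truth
    col = f"layer{layer}" if f"layer{layer}" in tr.columns else f"layer{layer}_label"
    truth_labels = tr.loc[list(m.cell_barcodes), col].to_numpy(dtype=object)

    reports = []
    for seed in seeds:
        valid = np.flatnonzero(pd.notna(truth_labels))
        idx = stratified_subsample(truth_labels[valid], "capped", cap=cap, seed=seed)
        idx = valid[idx]
        sub = m.subset_cells(idx)
        res = annotate_hierarchical(
            sub, hierarchy, params, prescreen=prescreen, max_layer=layer
        )
        pred = res.frame[f"layer{layer}_label"].where(
            res.frame[f"layer{layer}_label"].notna(), UNLABELLED
        )
        reports.append(evaluate(pred, truth_labels[idx]))
    return reports, mean_report(reports)
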