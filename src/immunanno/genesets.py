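"""Signature gene sets and the layered annotation taxonomy.

A :class:`GeneSet` is an ordered list of marker genes naming one cell type.
Sets are arranged into a :class:`SignatureHierarchy`: a three-layer tree
mirroring immune differentiation (major types at layer 1, their subtypes at
layer 2, CD4/CD8 T subtypes at layer 3) plus an immune / non-immune
pre-screen pair.  During annotation only sibling sets compete, so a
subtype's markers are weighed only against the other subtypes of the same
parent.

The canonical shipped taxonomy has 9 layer-1, 16 layer-2 and 13 layer-3
types; the bundled GMT carries small illustrative marker sets (canonical
markers such as CD3D/CD3E for T cells) meant as a template, not as the
curated production signatures, which users supply as their own GMT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, InputError
from .matrix_io import ExpressionMatrix, _open_text


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free collection of marker genes."""

    name: str
    genes: tuple

    def __init__(self, name: str, genes: Sequence) -> None:
        if not name:
            raise InputError("gene set name must be non-empty")
        genes = tuple(dict.fromkeys(str(g) for g in genes))  # de-dup, keep order
        if not genes:
            raise InputError(f"gene set {name!r} has no genes")
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, universe: Sequence) -> "GeneSet":
        """Subset to genes present in ``universe`` (order preserved)."""
        keep = set(universe)
        return GeneSet(self.name, [g for g in self.genes if g in keep])


@dataclass
class HierarchyNode:
    label: str
    gene_set: GeneSet
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SignatureHierarchy:
    """Tree of cell-type nodes plus an optional immune/non-immune pre-screen.

    Layer index (1-based) is the node's depth; sibling nodes compete with
    each other during annotation.
    """

    roots: list
    prescreen: Optional[Tuple[GeneSet, GeneSet]] = None  # (immune, non_immune)

    def __post_init__(self) -> None:
        labels = [n.label for n, _ in self.walk()]
        if len(set(labels)) != len(labels):
            seen, dup = set(), set()
            for l in labels:
                (dup if l in seen else seen).add(l)
            raise ConfigError(f"duplicate node labels in hierarchy: {sorted(dup)}")

    def walk(self) -> Iterator[Tuple[HierarchyNode, int]]:
        """Yield (node, layer) depth-first; layer starts at 1."""
        stack = [(n, 1) for n in reversed(self.roots)]
        while stack:
            node, layer = stack.pop()
            yield node, layer
            stack.extend((c, layer + 1) for c in reversed(node.children))

    def layer_counts(self) -> tuple:
        """Number of nodes per layer, e.g. (9, 16, 13) for the canonical tree."""
        counts: dict = {}
        for _, layer in self.walk():
            counts[layer] = counts.get(layer, 0) + 1
        return tuple(counts[k] for k in sorted(counts))

    @property
    def max_layer(self) -> int:
        return max(layer for _, layer in self.walk())

    def node(self, label: str) -> HierarchyNode:
        for n, _ in self.walk():
            if n.label == label:
                return n
        raise KeyError(label)

    def parent_of(self, label: str) -> Optional[str]:
        for n, _ in self.walk():
            for c in n.children:
                if c.label == label:
                    return n.label
        return None

    def labels(self, layer: int = None) -> list:
        return [n.label for n, l in self.walk() if layer is None or l == layer]

    def path_to(self, label: str) -> list:
        """Root-to-node label path, e.g. ['T', 'CD8_T', 'CD8_naive']."""
        path = [label]
        while (p := self.parent_of(path[0])) is not None:
            path.insert(0, p)
        return path

    def all_genes(self) -> set:
        genes = set()
        for n, _ in self.walk():
            genes.update(n.gene_set.genes)
        if self.prescreen:
            for s in self.prescreen:
                genes.update(s.genes)
        return genes


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: Union[str, Path]) -> list:
    """Parse a GMT file (name <TAB> description <TAB> gene...) into GeneSets.

    Descriptions are discarded; duplicate genes within a line are dropped
    keeping the first occurrence; duplicate set names are an error.
    """
    sets, names = [], set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name = fields[0]
            if name in names:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, [g for g in fields[2:] if g]))
    return sets


def write_gmt(sets: Sequence, path: Union[str, Path], description: str = "immunanno") -> None:
    with open(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# hierarchy construction


def build_hierarchy(
    sets: Sequence,
    tree_spec: Mapping,
    prescreen_labels: Optional[Tuple[str, str]] = None,
) -> SignatureHierarchy:
    """Assemble a validated hierarchy from gene sets and a parent->children map.

    ``tree_spec`` maps every node label to its (possibly empty) list of
    child labels; labels never appearing as children are the layer-1 roots.
    Every label, including the pre-screen pair, must have a matching
    GeneSet.  Cycles and repeated child labels are configuration errors.
    """
    by_name = {}
    for s in sets:
        if s.name in by_name:
            raise InputError(f"duplicate gene set name {s.name!r}")
        by_name[s.name] = s

    mentioned = list(tree_spec)
    child_labels = []
    for parent, children in tree_spec.items():
        for c in children:
            child_labels.append(c)
            if c not in mentioned:
                mentioned.append(c)
    dup_children = {c for c in child_labels if child_labels.count(c) > 1}
    if dup_children:
        raise ConfigError(f"labels with multiple parents: {sorted(dup_children)}")

    need = list(mentioned)
    if prescreen_labels is not None:
        need = list(prescreen_labels) + need
    missing = [l for l in need if l not in by_name]
    if missing:
        raise ConfigError(f"no gene set for labels: {missing}")

    child_set = set(child_labels)
    root_labels = [l for l in mentioned if l not in child_set]
    if not root_labels:
        raise ConfigError("tree_spec has no root labels (cycle?)")

    built: dict = {}

    def make(label: str, trail: tuple) -> HierarchyNode:
        if label in trail:
            raise ConfigError(f"cycle in tree_spec at {label!r}")
        if label in built:
            raise ConfigError(f"label {label!r} reached twice")
        node = HierarchyNode(label, by_name[label])
        built[label] = node
        for c in tree_spec.get(label, ()):
            node.children.append(make(c, trail + (label,)))
        return node

    roots = [make(l, ()) for l in root_labels]
    unreached = [l for l in mentioned if l not in built]
    if unreached:
        raise ConfigError(f"labels unreachable from any root (cycle?): {unreached}")

    prescreen = None
    if prescreen_labels is not None:
        prescreen = (by_name[prescreen_labels[0]], by_name[prescreen_labels[1]])
    return SignatureHierarchy(roots=roots, prescreen=prescreen)


def load_hierarchy_spec(path: Union[str, Path]) -> Tuple[dict, Optional[Tuple[str, str]]]:
    """Read a hierarchy config file (JSON: {"tree": {...}, "prescreen": {...}})."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "tree" not in cfg:
        raise ConfigError(f"hierarchy config {path} lacks a 'tree' mapping")
    prescreen = None
    if cfg.get("prescreen"):
        ps = cfg["prescreen"]
        try:
            prescreen = (ps["immune"], ps["non_immune"])
        except (TypeError, KeyError):
            raise ConfigError(
                "'prescreen' must map 'immune' and 'non_immune' to set names"
            ) from None
    return cfg["tree"], prescreen


def canonical_tree_spec() -> Tuple[dict, Tuple[str, str]]:
    """The shipped 9/16/13 immune taxonomy (tree mapping + prescreen pair)."""
    with resources.files("immunanno.data").joinpath("canonical_hierarchy.json").open() as fh:
        cfg = json.load(fh)
    return cfg["tree"], (cfg["prescreen"]["immune"], cfg["prescreen"]["non_immune"])


def load_canonical_hierarchy(sets: Optional[Sequence] = None) -> SignatureHierarchy:
    """Canonical taxonomy assembled from ``sets`` (default: bundled example GMT)."""
    tree, prescreen = canonical_tree_spec()
    if sets is None:
        with resources.as_file(
            resources.files("immunanno.data").joinpath("example_signatures.gmt")
        ) as p:
            sets = read_gmt(p)
    return build_hierarchy(sets, tree, prescreen)


# ---------------------------------------------------------------------------
# marker screening


@dataclass
class ScreeningConfig:
    """Thresholds for expression-based marker screening.

    ``min_mean_expression`` is applied to each gene's cross-dataset
    statistic: the unweighted mean over reference datasets of the gene's
    mean expression across that dataset's cells (0 where absent), i.e.
    datasets count equally regardless of size.  Default 0 keeps everything,
    making thresholds an explicit user decision; the report always carries
    the statistic so any cut-off is auditable.
    """

    min_mean_expression: float = 0.0
    min_set_size_after_screen: int = 1

    def __post_init__(self) -> None:
        if self.min_mean_expression < 0:
            raise InputError("min_mean_expression must be >= 0")
        if self.min_set_size_after_screen < 1:
            raise InputError("min_set_size_after_screen must be >= 1")


def screen_markers(
    sets: Sequence,
    reference_matrices: Sequence,
    cfg: ScreeningConfig = None,
) -> Tuple[list, pd.DataFrame]:
    """Drop low-expression marker genes based on reference datasets.

    Returns the surviving sets and a per-gene report with columns
    ``set, gene, statistic, removed, set_excluded``.  A set whose surviving
    genes fall below ``min_set_size_after_screen`` is excluded (flagged in
    the report, not an error).
    """
    cfg = cfg or ScreeningConfig()
    if not reference_matrices:
        raise InputError("screening requires at least one reference matrix")

    per_matrix_means = []
    for m in reference_matrices:
        means = np.asarray(m.counts.mean(axis=1)).ravel()
        per_matrix_means.append(dict(zip(m.gene_ids, means)))

    def statistic(gene: str) -> float:
        return float(np.mean([mm.get(gene, 0.0) for mm in per_matrix_means]))

    rows, kept_sets = [], []
    for s in sets:
        stats = {g: statistic(g) for g in s.genes}
        keep = [g for g in s.genes if stats[g] >= cfg.min_mean_expression]
        excluded = len(keep) < cfg.min_set_size_after_screen
        for g in s.genes:
            rows.append(
                {
                    "set": s.name,
                    "gene": g,
                    "statistic": stats[g],
                    "removed": g not in keep,
                    "set_excluded": excluded,
                }
            )
        if not excluded:
            kept_sets.append(GeneSet(s.name, keep))
        else:
            import warnings

            warnings.warn(
                f"gene set {s.name!r} excluded by screening "
                f"({len(keep)} genes survive, need {cfg.min_set_size_after_screen})",
                stacklevel=2,
            )
    return kept_sets, pd.DataFrame(rows)
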