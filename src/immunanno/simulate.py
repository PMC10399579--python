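"""Synthetic scRNA-seq count data with known hierarchical labels.

The generator emulates the structure of the benchmark datasets the
annotator is meant for: cells of known (hierarchically nested) immune
types whose type-specific signature genes are overexpressed against an
overdispersed count background.  Counts are negative binomial — the
standard overdispersed model for UMI counts — with mean ``baseline_mean``
for background genes and ``baseline_mean * marker_fold_change`` for the
markers of the cell's own leaf type *and all its ancestors* (a CD8 naive
cell also overexpresses CD8 T, T and pan-immune markers), which is what
makes layer-wise recovery meaningful.  Optional extra dropout forces
counts to zero independently.

It does not emulate batch effects, ambient RNA, doublets, library-size
variation or realistic gene-gene correlation; recovery on this data
validates the scoring/annotation machinery, not performance on real
tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, InputError
from .genesets import (
    GeneSet,
    SignatureHierarchy,
    build_hierarchy,
    canonical_tree_spec,
    write_gmt,
)
from .matrix_io import ExpressionMatrix

IMMUNE_SET = "Immune"
NON_IMMUNE_SET = "Non_immune"


@dataclass
class SimulationConfig:
    """World description for one simulated dataset.

    dispersion is the negative-binomial size (shape) parameter: variance
    = mu + mu^2 / dispersion, so smaller values mean more overdispersion.
    ``n_nonimmune`` defaults to ``cells_per_leaf`` when the hierarchy has a
    pre-screen pair (so the immune/non-immune decision is exercised), else 0.
    """

    hierarchy: SignatureHierarchy
    cells_per_leaf: int = 200
    n_background_genes: int = 200
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    marker_fold_change: float = 8.0
    dropout_extra: float = 0.0
    seed: int = 0
    n_nonimmune: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cells_per_leaf < 1:
            raise ConfigError("cells_per_leaf must be >= 1")
        if self.marker_fold_change < 1:
            raise ConfigError("marker_fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if not 0 <= self.dropout_extra < 1:
            raise ConfigError("dropout_extra must be in [0, 1)")
        if self.n_background_genes < 0:
            raise ConfigError("n_background_genes must be >= 0")

    def resolved_nonimmune(self) -> int:
        if self.n_nonimmune is not None:
            return self.n_nonimmune
        return self.cells_per_leaf if self.hierarchy.prescreen else 0


@dataclass
class SimulatedDataset:
    """Counts plus the full truth label path per cell and the config used."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # barcode, prescreen, layer1..layer3, leaf
    config: SimulationConfig

    def write(self, outdir: Union[str, Path]) -> dict:
        """Write MTX triplet + GMT + hierarchy spec + truth CSV; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.mtx",
            "features": outdir / "features.tsv",
            "barcodes": outdir / "barcodes.tsv",
            "gmt": outdir / "signatures.gmt",
            "hierarchy": outdir / "hierarchy.json",
            "truth": outdir / "truth.csv",
        }
        m = self.matrix
        counts = m.counts if sp.issparse(m.counts) else sp.csr_matrix(m.counts)
        from scipy.io import mmwrite

        mmwrite(str(paths["matrix"]), counts.astype(int), field="integer")
        paths["features"].write_text("".join(f"{g}\n" for g in m.gene_ids))
        paths["barcodes"].write_text("".join(f"{b}\n" for b in m.cell_barcodes))

        h = self.config.hierarchy
        sets = [n.gene_set for n, _ in h.walk()]
        tree = {n.label: [c.label for c in n.children] for n, _ in h.walk()}
        spec = {"tree": tree}
        if h.prescreen:
            sets = list(h.prescreen) + sets
            spec["prescreen"] = {
                "immune": h.prescreen[0].name,
                "non_immune": h.prescreen[1].name,
            }
        write_gmt(sets, paths["gmt"], description="synthetic")
        paths["hierarchy"].write_text(json.dumps(spec, indent=1))
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw a labelled dataset from the stated world (reproducible under seed)."""
    h = cfg.hierarchy
    rng = np.random.default_rng(cfg.seed)

    # gene universe: pre-screen markers, hierarchy markers (walk order), background
    genes: list = []
    seen: set = set()

    def add(gs) -> None:
        for g in gs:
            if g not in seen:
                seen.add(g)
                genes.append(g)

    if h.prescreen:
        add(h.prescreen[0].genes)
        add(h.prescreen[1].genes)
    for node, _ in h.walk():
        add(node.gene_set.genes)
    add(f"BG{i:05d}" for i in range(cfg.n_background_genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    leaves = [node for node, _ in h.walk() if node.is_leaf]
    groups: list = []  # (group label, path dict, upregulated gene indices)
    for leaf in leaves:
        path = h.path_to(leaf.label)
        up: set = set()
        if h.prescreen:
            up.update(gene_index[g] for g in h.prescreen[0].genes)
        for lab in path:
            up.update(gene_index[g] for g in h.node(lab).gene_set.genes)
        truth = {"prescreen": "immune" if h.prescreen else None, "leaf": leaf.label}
        for k, lab in enumerate(path, start=1):
            truth[f"layer{k}"] = lab
        groups.append((leaf.label, truth, sorted(up), cfg.cells_per_leaf))

    n_non = cfg.resolved_nonimmune()
    if n_non:
        if not h.prescreen:
            raise ConfigError("n_nonimmune > 0 requires a pre-screen pair")
        up = sorted(gene_index[g] for g in h.prescreen[1].genes)
        groups.append(
            ("non_immune", {"prescreen": "non_immune", "leaf": "non_immune"}, up, n_non)
        )

    blocks, barcodes, truth_rows = [], [], []
    for label, truth, up, n_cells in groups:
        mu = np.full(n_genes, cfg.baseline_mean)
        mu[up] = cfg.baseline_mean * cfg.marker_fold_change
        p = cfg.dispersion / (cfg.dispersion + mu)
        counts = rng.negative_binomial(
            cfg.dispersion, p[:, None], size=(n_genes, n_cells)
        )
        if cfg.dropout_extra > 0:
            counts[rng.random(counts.shape) < cfg.dropout_extra] = 0
        blocks.append(counts)
        for i in range(n_cells):
            barcodes.append(f"{label}.{i:05d}")
            truth_rows.append(dict(truth))

    matrix = ExpressionMatrix(
        gene_ids=genes,
        cell_barcodes=barcodes,
        counts=np.concatenate(blocks, axis=1).astype(float),
    )
    truth_df = pd.DataFrame(truth_rows)
    truth_df.insert(0, "barcode", barcodes)
    for k in (1, 2, 3):
        if f"layer{k}" not in truth_df.columns:
            truth_df[f"layer{k}"] = None
    truth_df = truth_df[
        ["barcode", "prescreen", "layer1", "layer2", "layer3", "leaf"]
    ]
    return SimulatedDataset(matrix=matrix, truth=truth_df, config=cfg)


# ---------------------------------------------------------------------------
# fixture hierarchies with synthetic marker genes


def _synthetic_sets(
    labels: Sequence, genes_per_set: int, shared: int = 0, prefix: str = ""
) -> list:
    """One disjoint synthetic gene set per label, optionally with a shared block."""
    pool = [f"{prefix}SHARED_g{j:03d}" for j in range(shared)]
    out = []
    for lab in labels:
        own = [f"{prefix}{lab}|g{j:03d}" for j in range(genes_per_set - shared)]
        out.append(GeneSet(lab, pool + own))
    return out


def make_fixture_hierarchy(
    n_major: int,
    n_children: Optional[Mapping] = None,
    genes_per_set: int = 10,
    disjoint: bool = True,
    overlap_fraction: float = 0.0,
    prescreen: bool = True,
) -> SignatureHierarchy:
    """Small synthetic taxonomy: ``n_major`` roots, optional nested children.

    ``n_children`` maps a label to its number of children; keys may name
    generated children ("M1_2") to nest deeper.  With ``disjoint=False``
    every set shares ``overlap_fraction`` of its genes from a common pool.
    """
    if n_major < 2:
        raise InputError("n_major must be >= 2")
    if genes_per_set < 1:
        raise InputError("genes_per_set must be >= 1")
    shared = 0
    if not disjoint:
        shared = int(round(overlap_fraction * genes_per_set))
        if shared >= genes_per_set:
            raise InputError("overlap_fraction leaves no set-specific genes")

    tree: dict = {f"M{i + 1}": [] for i in range(n_major)}
    for parent, k in (n_children or {}).items():
        if parent not in tree:
            raise ConfigError(f"n_children names unknown label {parent!r}")
        kids = [f"{parent}_{j + 1}" for j in range(int(k))]
        tree[parent] = kids
        for c in kids:
            tree.setdefault(c, [])
    labels = list(tree)
    sets = _synthetic_sets(labels, genes_per_set, shared)
    ps_labels = None
    if prescreen:
        sets += _synthetic_sets([IMMUNE_SET, NON_IMMUNE_SET], genes_per_set)
        ps_labels = (IMMUNE_SET, NON_IMMUNE_SET)
    return build_hierarchy(sets, tree, ps_labels)


def canonical_fixture_hierarchy(genes_per_set: int = 10) -> SignatureHierarchy:
    """The canonical 9/16/13 taxonomy with disjoint synthetic marker genes.

    Same tree shape and labels as the shipped taxonomy, but every set gets
    its own synthetic genes so recovery experiments have a known signal.
    """
    tree, (imm, non) = canonical_tree_spec()
    labels = list(tree)
    for kids in tree.values():
        labels.extend(k for k in kids if k not in labels)
    sets = _synthetic_sets(list(dict.fromkeys(labels)), genes_per_set)
    sets += _synthetic_sets([imm, non], genes_per_set)
    return build_hierarchy(sets, tree, (imm, non))


def load_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    """Read a SimulationConfig from JSON.

    The "hierarchy" key is either "canonical" (canonical shape, synthetic
    genes) or a mapping of :func:`make_fixture_hierarchy` arguments.
    """
    with open(path) as fh:
        raw = json.load(fh)
    hspec = raw.pop("hierarchy", "canonical")
    if hspec == "canonical":
        h = canonical_fixture_hierarchy(genes_per_set=raw.pop("genes_per_set", 10))
    elif isinstance(hspec, dict):
        h = make_fixture_hierarchy(**hspec)
    else:
        raise ConfigError(f"unrecognized hierarchy spec {hspec!r}")
    try:
        return SimulationConfig(hierarchy=h, **raw)
    except TypeError as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from None
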