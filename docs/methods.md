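# Methods

## Model

`immunanno` annotates immune cell types in scRNA-seq count matrices by
per-cell signature-set enrichment.  The underlying assumption is that a
cell type is characterized by coordinate up-regulation of a curated marker
set, and that immune identity is organized as a differentiation tree: a
CD8 naive cell is also a CD8 T cell, a T cell, and an immune cell.  Each
annotation decision is therefore a competition among *siblings* of the
tree only — subtype markers are never weighed against unrelated types,
which is what makes subtype calls stable in mixed tissues.

### Enrichment statistic

For one cell, genes are ranked by expression (largest value → rank `N`).
For a gene set `S` the score is the summed difference between the
rank-weighted in-set ECDF and the uniform out-of-set ECDF along the ranked
list (see the `ssgsea` module docstring for the formula).  Constants:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.25 | rank-weight exponent of the published ssGSEA variant; `0` weighs all in-set genes equally |
| `tie_method` | `"average"` | tied expression values share the mean rank; `"ordinal"` breaks ties by ascending gene index |
| `normalize_scores` | off | divide all scores by the global max−min range; cosmetic, cannot change an argmax |
| `min_genes_present` | 1 | sets with fewer genes present in the matrix are dropped; a warning is emitted below 3 because tiny overlaps make the score unstable |

The running sum is evaluated in closed form (two matrix products per cell
block) and is tested entrywise against an independent positional-loop
oracle to 1e-9.

**Ties and the walk order.**  The walk visits genes in decreasing rank;
among tied ranks the order is fixed as ascending gene index.  This makes
results deterministic and matches the order()-based behaviour of the
standard R implementation, but it means scores of tied genes depend on
gene row order: gene-order permutation invariance holds exactly only for
tie-free expression vectors.  Label changes from this effect require a
near-tie between competing sets; the property tests use tie-free data,
and the all-zero-cell case (every gene tied) is handled separately by
labelling such cells `unassigned` instead of scoring them.

**Rank-only dependence.**  Because only within-cell ranks enter the
statistic, any strictly increasing per-cell transform (log1p, CPM scaling)
leaves every score and label unchanged.  Input matrices therefore require
no normalization, and the package applies none.

### Hierarchical annotation

1. Optional pre-screen: argmax over the immune / non-immune pair.  The
   pre-screen cannot fail silently — an unscorable pre-screen set is a
   configuration error; users disable it explicitly for datasets from
   which non-immune cells were already removed.
2. Layer 1: immune cells compete among the 9 major-type sets.
3. Layers 2–3: each labelled group is re-scored among the children of its
   winning type.  Leaf types (Mast, Neutrophil, Plasma, …) stop deepening.

Ties at any argmax go to the earlier set in the declared hierarchy order,
with margin 0 recorded so downstream users can filter.  There is no
"unknown" call by design — the method always assigns the best-scoring
type; an optional `min_margin` filter (off by default) can withhold
low-confidence decisions as an extension.  Scores are per-cell, so
annotating a subset of cells reproduces the full-matrix labels exactly.

Per-type plot-data tables are emitted only for types with at least 50
cells (the CLI `--plot-data` flag); the annotation CSV itself is always
complete.

## Taxonomy and gene sets

The canonical tree has 9 layer-1 types (T, B, Monocyte, Macrophage, DC,
NK, ILC, Mast, Neutrophil), 16 layer-2 subtypes (under T, B, Monocyte,
Macrophage, DC, NK, ILC) and 13 layer-3 T subtypes (8 under CD4_T, 5
under CD8_T), plus the immune/non-immune pre-screen pair.  The shipped
`example_signatures.gmt` provides small illustrative canonical-marker
sets for every label (CD3D/CD3E for T, CD79A/CD79B/MS4A1 for B, LYZ/CD14
for monocytes, …).  These are a template demonstrating the GMT contract,
not validated production signatures; serious use requires a curated GMT.
Gene identifiers are matched by exact string equality — users must
harmonize symbol dialects (or Ensembl IDs) between matrix and GMT
themselves.

### Marker screening

The screening statistic for a gene is the *unweighted mean over reference
datasets* of its per-dataset mean expression (0 where absent): datasets
count equally regardless of cell number, reflecting dataset-level
averaging.  Raw values are averaged as provided; no normalization precedes
screening.  The default threshold is 0 (keep everything) because no
principled universal cut-off exists; the report always contains the
statistic so any chosen threshold is auditable.  Screening is idempotent,
and a set whose survivors fall below `min_set_size_after_screen` is
excluded with a warning rather than an error.

## Synthetic data generator

The simulator draws, for every leaf type, `cells_per_leaf` cells whose
counts are negative binomial: mean `baseline_mean` for background genes
and `baseline_mean × marker_fold_change` for the markers of the leaf *and
all its ancestors* (including the immune pre-screen set), which encodes
the biological premise that subtype identity implies parent identity and
makes layer-wise recovery meaningful.  `dispersion` is the NB size
parameter (variance = μ + μ²/dispersion).  Defaults — baseline mean 1,
dispersion 2, fold-change 8, 200 cells per leaf, 200 background genes,
10-gene disjoint sets — describe a clearly recoverable but overdispersed,
zero-heavy regime typical of UMI data; non-immune cells (one group of
`cells_per_leaf` cells overexpressing the non-immune set) are included by
default so the pre-screen is exercised.

The generator does **not** emulate batch effects, ambient RNA, doublets,
library-size variation, or realistic gene–gene correlation, and real
marker sets are neither disjoint nor uniformly expressed.  A green
recovery test therefore establishes that the scoring and annotation
machinery is correct, not that any particular accuracy will be achieved
on real tissue data.

At fold-change 1 the simulated world carries no signal; predictions are
then independent of truth, so the expected macro accuracy equals
1/(number of majors) regardless of any tie-induced bias in the prediction
marginals (the per-class recalls average to the prediction distribution,
which sums to 1).  The null test exploits this with a 4-standard-error
binomial band.

## Evaluation protocol

Truth labels are harmonized through an explicit total map; ambiguous
labels (doublet calls such as "NK/T") map to the DISCARD sentinel and are
excluded from all metrics but counted.  Stratified subsampling supports
the tiered rule (per type: >50,000 cells → 12,000; 20,000–50,000 →
8,000; otherwise all — the 10,000–20,000 band is kept whole as the
conservative reading of an unstated case, and boundary counts fall into
the smaller tier) and a flat per-type cap (default 3,000) for replicated
benchmarks, which average metrics arithmetically over (by default) five
seeded replicates.  Micro (cell-weighted) and macro (per-class-averaged)
metrics are both reported; per-layer metrics are restricted to cells
whose truth is labelled at that layer, and cells the annotator left
unlabelled at an evaluated layer count as a distinct `(unlabelled)`
prediction rather than being dropped.

## Numerical and design choices

- Duplicate gene symbols are collapsed at read time, default policy
  `sum` (conserves total counts); `max` and `first` are available.
- Matrix values are accepted as non-negative reals, not only integers,
  since normalized input is explicitly supported.
- All-zero cells are retained at read time and labelled `unassigned` by
  the annotator.
- The annotation CSV carries a `prescreen_label` column in addition to
  the per-layer label/score pairs so non-immune and unassigned outcomes
  survive a round trip.
- Randomness: every stochastic component (simulator, subsampler) takes an
  explicit seed and is bit-reproducible under it.

## Known limitations

- No novel-type detection: every immune cell receives the best-scoring
  known label, however poor the best score.
- Layer-3 discrimination is only as good as the CD4/CD8 subtype sets;
  with the illustrative GMT it is a demonstration, not a validated
  classifier.
- γδ T cells, eosinophils and basophils are absent from the canonical
  taxonomy.
- Tie handling gives earlier gene rows a deterministic advantage among
  exactly tied values (see above); this matters only for degenerate,
  near-signal-free inputs.
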