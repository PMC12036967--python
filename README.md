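# scattack

Adversarial-attack toolkit for single-cell RNA-seq cell-type classifiers.

Machine-learning annotators for scRNA-seq data (marker scoring, SVMs, random
forests, neural networks) are increasingly proposed for biomedical use, which
raises a practical question: how little does the input expression matrix have
to change — through technical noise, processing errors, or deliberate
manipulation — before the predicted cell type of a cluster flips?  `scattack`
answers this for *any* classifier that can be wrapped behind a narrow
black-box contract, with attack algorithms designed to be frugal with
classifier evaluations (cell-type classification is slow, so every algorithm
is call-budgeted).

## The model

A classifier is a function `(X, labels, m) → (k′, score, Ŷ, k̂)` where `X` is a
genes × cells matrix, `m` a target cluster, `Ŷ` a cells × cell-types score
matrix, `k̂` the per-cell argmax predictions and `k′` the cluster-level
prediction.  On top of this contract the package implements:

- **single-gene** (`adv_single_gene`): find *every* gene whose modification
  alone re-labels the cluster.  Genes are partitioned into `n_bins`
  contiguous bins (default 100), each bin is modified wholesale and
  classified once, and flipping bins are narrowed by a call-frugal recursive
  dichotomy (a non-flipping half certifies its genes clean; sibling checks
  are pooled into single classifications).  With one attackable gene among
  20 000 this needs at most `100 + ⌈log₂ 200⌉ + 2` classifier runs, and
  exactly 100 runs when nothing is attackable.
- **max-change** (`adv_max_change`): modify as many genes as possible without
  changing the prediction; the untouchable complement is the cluster
  *signature*.  Recursion stops at `max_split_size` genes (precision vs cost).
- **CGD** (`adv_cgd`): cluster-based gradient descent.  For gene j′ and cell
  value x the probe is `f(x) = (1 + α·sign(x))·x + ε`; the finite-difference
  score change drives one-gene-per-step updates
  `x ← (1 + α·sign(x)·sign(slope))·x + ε·sign(slope)` until the second most
  likely cell type of the cluster overtakes the first.  An augmented mode
  keeps iterating for accuracy/dynamics analyses.
- **random-walk / grid** (`adv_random_walk_min_change`, `adv_grid_min_change`):
  seeded stochastic search for 1-minimal gene × modification combinations,
  and exhaustive enumeration of all `(|mods|+1)^n − 1` assignments for < 10
  genes.
- **overview** (`survey`): quick whole-dataset sweep (20 initial bins,
  dichotomy halted at 100-gene blocks, `max_split_size=100`).

Modifications: `perc1`/`perc99` (replace by the gene's 1st/99th percentile),
`decile±N` (shift each value by N/10 of empirical quantile rank), `random`
(uniform between gene min and max), `aberrant±` (±10⁵ × dataset maximum), and
arbitrary `custom` transforms (e.g. `dropout_custom`).  Gene prioritization
for CGD and SVM-style feature selection comes from `get_sign_genes`, a
pairwise Welch-t ranking interleaved across every cluster pair.

## Worked example

```python
from scattack import (SyntheticSpec, make_synthetic_dataset, make_marker_classifier,
                      ModificationSpec, adv_single_gene, adv_max_change,
                      adv_cgd, PerturbationParams)

spec = SyntheticSpec(n_genes=500, n_clusters=3, cells_per_cluster=40, seed=0)
matrix, labeling, markers = make_synthetic_dataset(spec)
clf = make_marker_classifier(markers)          # scType-like marker voting

res = adv_single_gene(matrix, labeling, "clust1", clf,
                      ModificationSpec("perc99"), n_bins=20)
print(res.hits, res.classifier_calls)          # [] 26

mc = adv_max_change(matrix, labeling, "clust1", clf, ModificationSpec("perc99"))
print(mc.signature, mc.classifier_calls)       # ['g00414', 'g00486'] 32

cgd = adv_cgd(matrix, labeling, "clust1", clf, PerturbationParams(alpha=1, eps=1))
print(cgd.success, cgd.final_label, cgd.tested_genes, cgd.modified_genes)
# True clust3 6 4
```

Reading the numbers: this marker-voting classifier has no single-gene
vulnerability for `perc99` on `clust1` (empty hit list after 26 calls: 20
bins + dichotomy into false-positive-free flips), but switching on just the
two genes `g00414`/`g00486` — markers of the two competing cell types — is
enough to re-label the cluster, so they form its signature.  CGD flips the
cluster to `clust3` after testing 6 genes and modifying 4, all of them
planted `clust3` markers: the attack's gene selectivity exposes which inputs
the model actually uses.

The same flows are scriptable via the `scattack` CLI (`simulate`,
`rank-genes`, `single-gene`, `max-change`, `cgd`, `random-walk`, `grid`,
`overview`), reading MatrixMarket + TSV sidecars or dense CSV/TSV and writing
JSON/CSV reports.

## Documentation

`docs/methods.md` describes the algorithms, their assumptions, the synthetic
data generator and the numerical conventions in detail.
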