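# stemsvm

Kernel-SVM classification of genes involved in embryonic stem-cell
self-renewal and pluripotency, from heterogeneous genomics data:

- **Feature construction** — expression vectors over a 79-condition study
  layout (ES/EB means, two differentiation courses, an RA course, six
  knockdown courses), log2-scaled to unit norm; plus 12 TF-binding
  features per gene, either binary (peak within a TSS window) or
  continuous (distance-decay weighted peak-intensity sum,
  `a = Σ g_k · exp(−d_k/d0)`, log-transformed and quantile-normalized).
- **Kernel engine** — linear, polynomial (d = 3), and Gaussian RBF Gram
  matrices; RBF width by median-closest-negative heuristic or a
  log-uniform grid; F1-weighted combination of per-data-type kernels.
- **Classifiers** — SVM on precomputed kernels (scikit-learn dual
  solver), plus LDA, entropy decision tree, a 5-hidden-unit neural net
  (accuracy averaged over repeated initializations), and an ES/EB
  fold-change rule as baselines.
- **Evaluation** — leave-one-out cross-validation with optional nested
  hyperparameter selection, confusion metrics, stratified 3-fold
  ROC/AUC, Spearman rank correlation, Fisher's-exact overlap tests.
- **SVM-RFE** — recursive feature elimination with the kernel-space
  margin-change criterion (exactly `w_j²` for the linear kernel).
- **Prioritization** — predicted-positive fractions of candidate gene
  lists and their signal-to-noise ratio, persistent false-positive
  detection, and group comparison by t-test.
- **Synthetic data** — a seeded generator for the full data structure
  (gene universe, expression matrix, 12 peak sets, planted-enrichment
  candidate lists), so every stage is testable offline.

## CLI

All stages are exposed under a single `stemsvm` entry point:

```sh
stemsvm simulate --out data/ --n-pos 46 --n-neg 70 --n-unlabeled 110 --seed 1
stemsvm featurize --data data/ --mode combined_contin --out feats
stemsvm loocv --data data/ --mode micro --kernel RBF --out loocv.tsv
stemsvm roc --data data/ --mode micro --kernel RBF --out roc.tsv
stemsvm rfe --data data/ --mode simple_contin --kernel linear --out rfe.tsv
stemsvm prioritize --data data/ --mode micro --kernel RBF \
    --positives data/candidates_pos.txt --negatives data/candidates_neg.txt \
    --out prio.tsv
stemsvm grid --data data/ --out grid.tsv          # full 7 modes x 3 kernels
```

Data modes are `micro`, `chip_binary`, `chip_contin`, `simple_binary`,
`simple_contin` (concatenation) and `weight_binary`, `weight_contin`
(F1-weighted two-kernel combination); kernels are `linear`, `poly`,
`RBF`. Every output table carries a `# config_hash/seed/version` header.

The curated training gene list (46 positive / 70 negative symbols) ships
as package data and loads via `stemsvm.experiment.load_training_genes()`.

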