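# Workflow template: peripheral-blood gene expression, early breast-cancer
# detection (GEO accession GSE16443; 130 samples: 67 cases, 63 controls,
# 11217 probes after normalization).
#
# This template documents the double cross-validation workflow for a real
# high-dimensional dataset.  The expression matrix is NOT shipped with the
# package: download the normalized series matrix from GEO, transpose it to
# samples-as-rows, add a binary `label` column (1 = case, 0 = control) and
# save as CSV.  Then run:
#
#   rankbag cv --data gse16443.csv --label-col label \
#       --spec SVM --spec PLR --spec PLS+RF --spec PLS+LDA \
#       --spec PLS+QDA --spec PCA+QDA \
#       --folds 10 --n-bootstrap 101 --seed 1
#
# The outer 10-fold CV estimates performance; inside every outer training
# fold the ensemble performs its own bootstrap/OOB model selection (a nested
# cross-validation), so no test information leaks into the selection.
# Expect hours of compute at p ~ 11k; reduce --n-bootstrap for a pilot run.

data:
  source: "GEO accession GSE16443 (download required; not bundled)"
  file: gse16443.csv           # user-prepared, samples as rows
  label_column: label
  positive_class: 1

methods:
  specs: [SVM, PLR, PLS+RF, PLS+LDA, PLS+QDA, PCA+QDA]
  n_components: 5
  ensemble:
    n_bootstrap: 101
    measures: [accuracy, sensitivity, specificity]
    weights: [1, 1, 1]
    distance: footrule
    aggregator: brute

evaluation:
  outer_folds: 10
  stratified: true
  seed: 1
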