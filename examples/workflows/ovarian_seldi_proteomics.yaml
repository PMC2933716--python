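# Workflow template: ovarian-cancer SELDI-TOF proteomics screening
# (100 cases / 100 controls; 15200 m/z intensities per spectrum, m/z range
# 0-20000).
#
# The spectra are NOT shipped: obtain the public ovarian dataset, arrange it
# samples-as-rows with a binary `label` column (1 = case) and save as CSV.
# Then run the 5-fold external CV used for datasets of this size:
#
#   rankbag cv --data ovarian_seldi.csv --label-col label \
#       --spec RF --spec SVM --spec PLS+RF --spec PLS+LDA --spec PLS+QDA \
#       --folds 5 --n-bootstrap 101 --seed 1
#
# Caveat recorded in the literature: the discriminatory signal in this
# dataset may be partly non-biological (batch/run-order artifacts), so treat
# it purely as a classification benchmark, not as biology.
# At p = 15200 a full run takes many hours, dominated by the forest members.

data:
  source: "public ovarian SELDI-TOF case-control study (download required; not bundled)"
  file: ovarian_seldi.csv
  label_column: label
  positive_class: 1

methods:
  specs: [RF, SVM, PLS+RF, PLS+LDA, PLS+QDA]
  n_components: 5
  ensemble:
    n_bootstrap: 101
    measures: [accuracy, sensitivity, specificity]
    weights: [1, 1, 1]
    distance: footrule
    aggregator: brute

evaluation:
  outer_folds: 5
  stratified: true
  seed: 1
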