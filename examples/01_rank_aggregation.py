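"""Combine conflicting performance rankings into one consensus ordering.

Three performance measures rank four classifiers differently; weighted rank
aggregation finds the ordering minimizing the weighted sum of Spearman
footrule distances to the three input lists.
"""

import rankbag as rb

# accuracy, sensitivity and specificity each produce an ordering, best first
by_accuracy = ("SVM", "RF", "LDA", "QDA")
by_sensitivity = ("RF", "SVM", "QDA", "LDA")
by_specificity = ("SVM", "LDA", "RF", "QDA")

problem = rb.AggregationProblem(
    lists=(by_accuracy, by_sensitivity, by_specificity),
    weights=(1.0, 1.0, 1.0),          # equal importance of the three measures
    distance="footrule",
)

exact = rb.aggregate_brute_force(problem)
print(f"consensus ordering : {exact.best_order}")
print(f"objective Phi      : {exact.objective}")

# the stochastic optimizers find the same optimum and are seed-reproducible
ce = rb.aggregate_cross_entropy(problem, seed=0)
ga = rb.aggregate_genetic(problem, seed=0)
print(f"cross-entropy      : {ce.best_order}  Phi={ce.objective}")
print(f"genetic            : {ga.best_order}  Phi={ga.objective}")

# doubling the weight on sensitivity can promote the sensitivity leader
weighted = rb.AggregationProblem(
    lists=(by_accuracy, by_sensitivity, by_specificity),
    weights=(1.0, 4.0, 1.0),
    distance="footrule",
)
print(f"sensitivity-weighted winner: {rb.best_algorithm(weighted)}")
# The winner is the algorithm a practitioner should prefer when all listed
# measures matter simultaneously, at the stated relative importances.
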