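"""Train the adaptive ensemble on a threenorm sample and inspect it.

Each of the 21 bootstrap rounds fits all components in-bag, ranks them on
out-of-bag accuracy/sensitivity/specificity, and keeps the rank-aggregation
winner; prediction is a majority vote of the kept models.
"""

import rankbag as rb

train = rb.threenorm(n=100, d=200, rng=1)
test = rb.threenorm(n=200, d=200, rng=2)

specs = [rb.make_spec(n) for n in ("PLS+LDA", "PCA+LDA", "RF")]
config = rb.EnsembleConfig(specs=specs, n_bootstrap=21, seed=7)
model = rb.train_ensemble(train.X, train.y, config)

print("selection counts over 21 bootstraps:", model.selection_counts())
# the supervised PLS projection should dominate the unsupervised PCA one

pred = model.predict(test.X)
proba = model.predict_proba(test.X)
acc = (pred == test.y).mean()
auc = rb.roc_auc(test.y, proba[:, 1])
print(f"test accuracy : {acc:.3f}")
print(f"test AUC      : {auc:.3f}   (vote-proportion scores)")
print("first five vote proportions for class 1:", proba[:5, 1].round(3))
# each proportion is a multiple of 1/21: the fraction of kept models voting 1
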