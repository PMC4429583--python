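"""Random-forest permutation importance of turn-timing predictors.

Runs the full pipeline on a 60-conversation synthetic corpus and fits a
regression forest of significance-gated trees (each tree sees a
bootstrap sample and 3 random predictors). A predictor's importance is
the mean out-of-bag MSE increase when its column is permuted, normalized
by the SD of the per-tree increases; the smallest absolute value serves
as a baseline for spurious effects.
"""

import numpy as np

from turntaking import (GeneratorConfig, RegressionForest, descriptives,
                        diagnostics, generate_corpus, permutation_importance,
                        process_corpus)
from turntaking.features import encode_features

corpus = generate_corpus(GeneratorConfig(n_conversations=60, seed=11))
ana = process_corpus(corpus.tokens_by_conv, corpus.lexicon,
                     corpus.unit_stats, corpus.parses, corpus.speakers)
df = ana.features
y = df["fto_ms"].to_numpy()
d = descriptives(y)
print(f"{len(df)} transfers | FTO mean {d['mean']:.0f} ms, "
      f"median {d['median']:.0f}, SD {d['sd']:.0f}, "
      f"KDE mode {d['mode_kde']:.0f}")

X, names = encode_features(df)
forest = RegressionForest(n_trees=500, m_try=3, seed=1).fit(X, y)
report = permutation_importance(forest, X, y, names=names)
print(f"\ntop 8 of {len(names)} predictors "
      f"(baseline for spurious effects = {report.baseline:.3f}):")
for row in report.table.head(8).itertuples():
    print(f"  {row.rank:2d}. {row.predictor:22s} {row.importance:6.2f}")

diag = diagnostics(X, y)
print(f"\nsingle significance-gated tree: r(predicted, observed) = "
      f"{diag.single_tree_r:.2f} over {diag.n_splits} splits")
print(f"gap/overlap sign accuracy: {100 * diag.gap_overlap_accuracy:.0f}% "
      f"(gap base rate {100 * np.mean(y >= 0):.0f}%)")
print(f"linear model R^2: {100 * diag.linear_r2:.1f}% "
      "(weak overall trends, stronger context-specific structure)")
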