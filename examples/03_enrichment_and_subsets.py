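"""Judge reported features by enrichment and predictive power.

Two complementary quality checks for any set of reported (meta-)features:
(1) hypergeometric enrichment of a data-derived known feature set along the
attribution ranking, and (2) test AUC of fresh classifiers trained on
growing top-ranked subsets versus random subsets of the same size.
"""

import gradpath as gp

data = gp.synth_tabular(n=400, p=200, n_informative=10, effect_size=5.0,
                        block_size=4, block_r=0.9, seed=0)
X, y = data.features, data.labels
mmap = gp.build_meta_features(X[y == 0], threshold=0.8)

# known set: meta-features with extreme presence skew between the classes
known = gp.known_feature_set(X, y, 1, 0, threshold=20, mmap=mmap)
print(f"known meta-feature set (-log10 p > 20): {len(known)} members")

# rank meta-features by their relative attribution share (here from a
# quick O-L zero-baseline run to keep the example fast)
codec, predictor = gp.train_reference_models(
    X.to_numpy(), y,
    gp.ModelConfig(q=32, ae_hidden=(96,), ae_epochs=600, head_epochs=800),
    seed=1,
)
G = gp.class_attributions(predictor, X[y == 1], gp.zero_baseline(200),
                          gp.PathConfig("O-L", 250))
ranked = gp.rank_by_relative_attribution(
    gp.meta_attributions(G, mmap)).index.tolist()

curve = gp.enrichment_curve(ranked, known, universe=len(mmap))
best = curve.loc[curve["minus_log10_p"].idxmax()]
print(f"peak enrichment -log10(p) = {best['minus_log10_p']:.2f} at the top "
      f"{int(best['subset_size'])} ranked meta-features")

subset = gp.feature_subset_curve(
    X, y, ranked, sizes=[1, 2, 5, 10, 20], repeats=20, seed=2,
    metric="auc", mmap=mmap,
)
print("\nsubset predictive power (test AUC):")
print(subset.table.to_string(index=False,
                             float_format=lambda v: f"{v:.3f}"))
print("\nThe ranked arm should reach near-perfect AUC within a few "
      "meta-features while equally sized random subsets lag — evidence the "
      "ranking concentrates the class signal.")
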