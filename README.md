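# gradpath

Feature attribution for differentiable predictors on tabular genomics data,
generalizing integrated gradients with **nonlinear paths**, **informed
baselines**, and a **statistical test for class-level significant
features** — plus the downstream analyses used to judge reported features:
hypergeometric enrichment, subset predictive-power curves, and positional
motif maps around cassette exons.

## Who this is for

Interpreting a trained model is a routine need in genomics: a splicing-code
model predicts tissue-specific exon inclusion from hundreds of curated
sequence features, and the scientific question is *which* features drive a
prediction — weak splice sites, conserved intronic windows, binding motifs
of RNA-binding proteins. Plain integrated gradients often answers poorly
here: a straight path from an all-zero baseline crosses regions of feature
space far from any real event (an exon of length 0 is not biology), and a
per-sample attribution vector gives no notion of statistical significance
for a class of events.

## The method

For a prediction function F over p features and a reference point x', the
attribution of feature j along a path γ from x' to x is

    attr_j(x) = ∫₀¹ ∂F(γ(α))/∂γ_j(α) · ∂γ_j(α)/∂α dα

realized on a discretized path with the trapezoidal rule. Any exact path
integral satisfies *completeness*, Σ_j attr_j = F(x) − F(x'), which the
package monitors as a per-result diagnostic together with step-halving
deltas (default operating point: 250 path points).

Extensions over the classic straight-line/zero-baseline recipe:

- **Paths** — four taxonomies, named by space × shape: `O-L` (linear,
  original space), `H-L` (linear between the autoencoder codes z' = E(x')
  and z = E(x), decoded back and bridged to the exact endpoints), `O-N` and
  `H-N` (Dijkstra shortest paths through a distance-weighted k-NN graph of
  training points, in original or latent space). Nonlinear paths stay near
  observed data, avoiding attribution artifacts from off-manifold regions.
- **Baselines** — group-agnostic: all-zero and *encoded-zero* (the decoder
  image of the zero latent vector, approximating the training mean);
  group-specific, drawn from a designated baseline class: random, k-means
  centroids, the points closest to the class median, or the points close to
  each sample (discarding the single closest as an outlier guard).
- **Significance** — features highly correlated with one another (e.g.,
  variants of one binding motif) are merged into *meta-features* by
  single-linkage grouping at |r| ≥ 0.8; a meta-feature's attribution is the
  sum of its members'. Per meta-feature, a one-sided Welch t-test compares
  absolute attributions of the class of interest against a similarly sized
  random event set, Bonferroni-corrected at FWER 0.05.

Reference models (a tanh autoencoder and a predictor whose first stage is
the frozen encoder) are implemented in numpy with analytic input gradients,
and any scalar model can be wrapped via `FunctionModel` (central finite
differences as fallback). Downstream modules add hypergeometric enrichment
curves, subset retraining curves, and motif-map analysis (per-position
3-mer frequencies, 20-nt sliding Fisher tests, crosslink-tag proximity).

## Worked example

```python
import gradpath as gp

data = gp.synth_tabular(n=400, p=200, n_informative=10, effect_size=5.0,
                        block_size=4, block_r=0.9, seed=0)
X, y = data.features, data.labels
codec, predictor = gp.train_reference_models(
    X.to_numpy(), y,
    gp.ModelConfig(q=32, ae_hidden=(96,), ae_epochs=600, head_epochs=800),
    seed=1)

mmap = gp.build_meta_features(X[y == 0], threshold=0.8)
base = gp.median_baseline(X[y == 0].to_numpy(), m=3)
cfg = gp.PathConfig("H-L", n_steps=250, codec=codec)
G = gp.class_attributions(predictor, X[y == 1], base, cfg)
R = gp.class_attributions(
    predictor, gp.sample_random_set(X, class_size=200, seed=2), base, cfg)
table = gp.significance_test(
    gp.meta_attributions(G, mmap), gp.meta_attributions(R, mmap), fwer=0.05)
print(len(table.significant))
```

Run as `python examples/02_significant_features.py`, this prints:

```
200 features grouped into 50 meta-features
significant meta-features at FWER 0.05: 10
planted blocks recovered: 10/10, false positives: 0
```

meaning the latent-linear path from three median baseline points attributed
the class difference to exactly the ten feature blocks that carry the
planted signal, with no spurious calls among the other forty. The other
scripts in `examples/` demonstrate path construction and completeness
diagnostics (`01`), enrichment and subset predictive-power curves (`03`),
and the motif-map / crosslink-proximity analysis (`04`). A thin CLI
(`gradpath synth|train|attribute|significance|enrich|evaluate|motifmap|stability`)
wires the same stages into file-based runs.

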