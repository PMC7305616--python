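# Methods

## Scope and model contracts

The package interprets any scalar differentiable prediction F : R^p → R by
path-integrated gradients. Two contracts define what a model must provide:
`PredictionFunction` (evaluate and gradient, batched where possible) and
`LatentCodec` (encoder E : R^p → R^q and decoder D : R^q → R^p, q < p).
Reference implementations are small dense tanh networks written in numpy
with analytic input gradients obtained by vector-Jacobian products; tanh is
used throughout so the prediction surface is C^∞ and the trapezoidal
quadrature converges at its nominal rate. `FunctionModel` wraps arbitrary
callables, falling back to central finite differences with per-coordinate
step h_j = 1e-5·max(1, |x_j|) when no analytic gradient is given (agrees
with analytic derivatives to ~1e-6 relative on smooth test functions).

The reference predictor is the composition head(E(x)) with the encoder
frozen after autoencoder training — one combined network in which paths can
be built in either the original or the latent space. The autoencoder
reconstruction loss is mean squared error; for binary class targets the
head trains with logistic loss and the attributed scalar is the logit.
Training is full-batch Adam (lr 1e-2), fully determined by a seed.

## Attribution integral

On a discretized path γ with points p_1 … p_n (p_1 = x', p_n = x, both
bit-exact), the attribution is computed per segment directly in feature
space:

    attr_j = Σ_i ½ (g_j(p_i) + g_j(p_{i+1})) (p_{i+1,j} − p_{i,j})

absorbing the ∂γ_j/∂α factor of the continuous line integral into the
coordinate increments. This form is exact for linear F on any polyline and
avoids differentiating the path parameterization. Two diagnostics accompany
every result: the completeness gap |Σ attr_j − (F(x) − F(x'))| and, in
`refine_until`, the maximum per-coordinate change under step doubling
(starting at n = 50). The default operating point is n = 250 points, at
which the reference models show completeness gaps below 0.2% of |ΔF| on all
four path kinds and step-halving movement below 0.2%. A non-converged
refinement returns the finest result flagged, rather than raising.

When a sample is attributed against several baseline points, the per-point
attribution vectors are averaged unweighted; the per-sample diagnostic
records the worst completeness gap among them. Pooling instead of averaging
is available to the significance stage via its inputs, but averaging is the
default because it keeps one row per sample.

## Paths

- **O-L**: uniform grid on the straight segment.
- **H-L**: straight segment between z' = E(x') and z = E(x) decoded back to
  feature space. Because D(E(·)) is lossy, the decoded curve misses the true
  endpoints by the reconstruction error; linear bridges x' → D(z') and
  D(z) → x close the gaps. Points are allocated to the three macro-segments
  proportionally to their lengths (the decoded core's length estimated from
  a 64-point pilot decoding), with a minimum of two core points.
- **O-N / H-N**: an undirected k-NN graph over reference points (edge if
  either endpoint is among the other's k nearest; weight = Euclidean
  distance; default k = 10). Both path endpoints are linked to their k
  nearest nodes (the opposite endpoint competes as a candidate, so a short
  direct hop is never excluded), the minimum-weight route is found with
  Dijkstra's algorithm (networkx), and n points are spread along the
  waypoint polyline proportionally to segment lengths with every waypoint
  kept. For latent graphs the routing happens between z' and z and the
  polyline is decoded with endpoint bridges as in H-L.

α is defined as normalized cumulative arc length of the final polyline
(exact coincident points are tie-broken by an infinitesimal index ramp so
the grid is strictly increasing).

Well-separated classes make the mutual k-NN graph fall apart into per-class
components at any moderate k, leaving cross-class paths undefined; by
default this raises an error advising a larger k. `knn_graph(...,
ensure_connected=True)` instead joins components through their single
closest cross-component pair — the smallest augmentation that restores a
well-defined shortest path, and the setting used for the synthetic studies
here. Point-allocation integers use the largest-remainder method, ties by
segment order, for determinism.

## Baselines

Group-agnostic: all-zero, and encoded-zero D(0_q), which for an autoencoder
trained on roughly centered data lands near the training mean (checked
empirically, not enforced). Group-specific selections happen in the
original feature space: uniform random rows (seeded, without replacement),
k-means centroids (scikit-learn, default k = 3, one reseed on an empty
cluster), the m rows nearest the coordinate-wise median (default m = 3),
and per-sample "close" baselines that rank class rows by distance to the
sample, discard the single nearest as an outlier guard, and keep the next
m. All ties break by input order.

## Significance testing

Meta-features are the connected components of the thresholded
absolute-Pearson-correlation graph (single-linkage grouping, default
|r| ≥ 0.8); constant columns become singletons with a warning. A
meta-feature's attribution is the sum of its members' signed attributions;
the test statistic uses its absolute value. The alternative "sum of
absolute member attributions" and a pooled-rank transform are available as
options. For each meta-feature, Set_G (class of interest) and Set_R (a
similarly sized random draw across all classes, seeded) are compared with a
one-sided Welch t-test for mean(Set_G) > mean(Set_R); Bonferroni correction
over the number of meta-features tested; default FWER 0.05 (0.01
selectable). When both sets have zero variance the p-value is reported as 1
(no evidence), not an error.

One practical caution, verified on simulations: completeness ties every
feature's attribution to the sample's F(x) − F(x'), so attributions of one
sample share a common magnitude factor and the 500 per-feature p-values of
a single split are positively dependent. The Bonferroni count behaves (0–1
significant under the null), but a Kolmogorov–Smirnov uniformity check of
raw p-values is only meaningful on exchangeable inputs with independent
columns — the calibration analyses therefore run the test directly on null
data groups, while the end-to-end attribution route is checked for its zero
Bonferroni count.

## Enrichment and predictive power

The known-feature set is built from the data: per feature (binarized at
value > 0, warning for continuous columns), a two-sided hypergeometric test
(2·min(tails), capped at 1) for presence skew between the positive and
negative class; features with −log10 p > 20 qualify — a deliberately
conservative cutoff — and a meta-feature inherits the minimum member
p-value. Enrichment curves report the upper-tail hypergeometric p of the
overlap between every prefix of the attribution-ranked meta-feature list
and the known set ("relative attribution" = mean absolute meta-attribution
normalized to sum 1). The subset curves retrain a fresh scikit-learn
logistic classifier per subset size on a fixed stratified 80/20 split
(accuracy or AUC-ROC), the random arm averaging 20 uniform draws per size;
meta-feature subsets expand to member features before training.

## Motif maps and crosslink proximity

Events are classified from a junction-level ΔΨ table (percent units):
regulated requires both an inclusion and an exclusion junction at
|ΔΨ| ≥ 10, split by the sign of the strongest inclusion junction;
non-regulated requires all junctions < 5; anything between is unassigned.
Three splice-site-anchored regions are analyzed per event — the last L nt
of the upstream intron (right-aligned at the 3' splice site), the cassette
exon (left-aligned), and the first L nt of the downstream intron
(left-aligned at the 5' splice site); sequences are uppercased RNA (T→U on
read). Motif tracks count, per aligned position, the fraction of events
with any of the query 3-mers (default AAU/UAA/AUU, the A1CF-binding
k-mers) starting there, the denominator restricted to events whose
sequence covers the position; display tracks use a centered 20-nt running
mean with truncated edge windows. Significant positional differences use a
20-nt sliding window (stride 1), a 2×2 Fisher exact test on
events-containing-a-motif-start-in-window per set, two-tailed p reported at
window centers with no cross-window correction (overlapping windows are
strongly dependent; the track is read as a profile). Crosslink proximity
retains transition sites with ≥ 2 unique tags and calls an event bound if
a retained site falls in the upstream 300 nt, the exon, or the downstream
300 nt (0-based half-open intervals, each region also reported
separately); sets are compared with two-tailed Fisher tests on
bound/unbound counts.

The splicing-code target transforms are provided for model builders:
T_Ψ = E[Ψ], T_ΔΨinc = |max(ε, E[ΔΨ])|, T_ΔΨexc = |min(−ε, E[ΔΨ])| with
ε ~ U(0.01, 0.03), so non-changing events carry small symmetric
differential targets instead of exact zeros.

## Latent stability

Robustness of an embedding is measured as the Spearman rank correlation of
the n(n−1)/2 pairwise Euclidean distances among encoded points across
codecs; rank-preserving re-embeddings score exactly 1 and independent
random embeddings scatter around 0. Identical points yield an undefined
correlation, reported as missing with a warning.

## Synthetic data

The generators define the study conditions and are first-class, seeded,
bit-reproducible code:

- **Tabular**: features in consecutive blocks of `block_size`, each column
  √r·factor + √(1−r)·noise so within-block correlation targets `block_r`
  (latent-factor construction guarantees a valid covariance at any p). One
  feature in each of `n_informative` distinct blocks is shifted by
  `effect_size`·noise_sd in class 1. Defaults n = 400, p = 200,
  10 informative, effect 5, blocks of 4 at r = 0.9. Note that any
  between-class mean shift also induces *pooled* cross-feature correlation
  through the class indicator, so meta-feature maps for recovery analyses
  are built on the baseline class only, where the block structure is
  unconfounded.
- **Images**: per-class stroke patterns on a 12×12 canvas with Bernoulli
  flip noise (keeps pixels in {0,1}; the truth mask for a class pair is
  exactly the symmetric difference of the patterns).
- **Sequences**: i.i.d. background nucleotides (uniform by default); the
  enriched arm plants one A/U-rich 3-mer per event with probability
  `planted_rate` at a uniform position in a designated window (default
  180–220 nt into the downstream intron), and emits matching crosslink
  tags (counts 2–4) at the planted genomic positions plus single-tag noise
  that the min-tag filter must remove.

What these generators do not emulate: realistic splice-site strength or
conservation features, non-Gaussian marginals of curated feature tables,
linkage between regions, or read-level noise. Passing recovery tests shows
the pipeline identifies planted mean-shift signal and positional motif
enrichment under clean conditions; it does not certify performance on
curated biological feature sets.

## Study-condition choices

- Reference model for axiom and quadrature checks: n = 300, p = 40 data,
  q = 8 codec. For the planted-recovery study (p = 200 with ~50 block
  factors) the codec uses q = 32 with a 96-unit hidden layer, trained 600
  epochs (head 800): latent paths are only meaningful when the autoencoder
  actually reconstructs the directions of interest, and a tighter
  bottleneck demonstrably drops planted feature directions, which the
  attribution then — correctly — reports as unused by the model.
- Significance defaults: FWER 0.05, Welch variant, |sum| meta-statistic.
- Subset-curve sign tests discard exact ties (standard sign-test
  convention); on perfectly separable data both arms saturate at AUC 1.0
  for large subsets and those sizes carry no information.
- log10 is assumed wherever thresholds are quoted as −log(p) (bioinformatics
  convention); the enrichment threshold default is 20.
- All problem sizes (50 sample/baseline pairs for axiom checks, 200 random
  graphs for routing oracles, 500 meta-features for calibration, 200
  events/arm for motif maps) were chosen as the package's own balance of
  statistical resolution against a desk-scale run; the full acceptance
  sweep completes in well under a minute.

## Known limitations

- Neighbor paths are polylines through observed points, not geodesics on a
  learned manifold; with `ensure_connected` bridges they can cross sparse
  regions exactly once.
- The significance test inherits the dependence structure of attributions
  (see above); its p-values are calibrated per meta-feature but not jointly
  independent across meta-features.
- Welch t-tests assume approximately normal group means; heavy-tailed
  attribution distributions at very small class sizes (< ~20) warrant the
  rank-transform variant.
- The reference networks are deliberately small; they are contracts-first
  stand-ins for production models, not tuned predictors.
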