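# Methods

`driverplex` prioritizes cancer driver genes on a *multiplex* of gene–gene
networks — several directed and undirected interaction layers (protein
interactions, regulatory edges, pathways, kinase–substrate relations, …)
over one shared gene universe — combined with a dense multi-omics feature
matrix. This note documents the model, its assumptions, the defaults, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Problem setting

Inputs are M binary adjacency layers A⁽ᵐ⁾ ∈ {0,1}ⁿˣⁿ over n genes (each
layer flagged directed or undirected; undirected edges are stored
bidirectionally), a feature matrix X ∈ ℝⁿˣᶠ of z-scored per-cancer-type
omics summaries (mutation frequency, mean tumor−normal methylation
difference, mean log₂ expression fold change; f = 3 × #cancer types), and a
list of known driver genes. The labeling regime is positive–unlabeled: the
positive list is small and trustworthy, no negative list exists, and the
unlabeled pool contains undiscovered drivers.

## Directional multiplex convolution

Each directed layer is normalized two ways:

    S_fwd = D_out^{-1/2} A D_in^{-1/2}      (messages along out-edges)
    S_bwd = D_in^{-1/2} Aᵀ D_out^{-1/2}     (messages along reversed arcs)

with (degree)^{-1/2} := 0 at degree 0, so isolated nodes neither send nor
receive messages and no non-finite values arise. For symmetric A both
operators equal the classical D^{-1/2} A D^{-1/2}; this is asserted in the
tests and is the basis of the directionality ablation (symmetrize every
layer, then encode).

Per node, per layer graph, a *directional gate* decides how much weight the
incoming vs outgoing aggregate receives. The gate fuses two signals:

* **Neighbor diversity** — a per-node directional Dirichlet energy,
  e = (I+S)(H⊙H) − 2((I+S)H⊙H − H⊙H), equal per node to
  Σⱼ sᵢⱼ (hᵢ−hⱼ)² + (1−Σⱼ sᵢⱼ) hᵢ², i.e. the feature discrepancy between a
  node and its in- (or out-) neighborhood. High energy in a direction
  suggests class disagreement with that neighborhood.
* **Degree diversity** — trainable embedding tables indexed by the raw in-
  or out-degree (clamped at `max_degree`, default 512). Tables are per
  layer, per graph, per direction; the gate projections (w, b) and the
  temperature τ are shared across graphs within a layer.

The gate logit is q_dir = (−e_dir + Deg_dir) w_dir + b_dir and the two
directions are normalized with a learnable-temperature two-way softmax,
computed as sigmoid((q_fwd − q_bwd)/τ): algebraically identical, stable,
and exactly complementary (Γ_bwd = 1 − Γ_fwd to machine precision). τ is
stored as log τ and initialized at 1.

The layer update averages gated messages over all M graphs with a residual:

    H' = α H + (1/M) Σₘ (Γ_fwd⁽ᵐ⁾ S_fwd⁽ᵐ⁾ H W_fwd + Γ_bwd⁽ᵐ⁾ S_bwd⁽ᵐ⁾ H W_bwd)

There is no elementwise nonlinearity — the gating is the nonlinearity
(a config switch can insert ReLU; default off). Because the input width f
differs from the hidden width, X is first lifted by a learnable input
projection so the α-residual is well-defined at every layer. α is fixed at
0.5. Dropout (default 0.5) is applied between hidden layers during
training only. Defaults: 3 layers, hidden 256.

## Contrastive pretraining with consensus

Before negative inference, an encoder is pretrained without labels. For
each layer graph, the encoder embeds the original features (positive view)
and a row-permuted corruption (negative view; one fresh permutation per
epoch). A per-graph bilinear discriminator M⁽ᵐ⁾ scores node embeddings
against the mean-pooled graph summary g⁽ᵐ⁾ of the positive view, with loss

    L_contrast = −(1/n) Σ_v log σ(h_{v,+} M g) − (1/n) Σ_v log σ(1 − h_{v,−} M g)

The second term is implemented exactly in this form; a config flag offers
the conventional log(1 − σ(score)) variant. Mean pooling runs over all
nodes of the positive view by default; a flag restricts it to labeled
positives (both readings of "pooling over the positive nodes" are exposed
rather than guessed). A learnable consensus matrix Z ∈ ℝⁿˣʰ is regularized
toward the mean positive-view embedding and away from the mean
corrupted-view embedding,

    L_consensus = ‖Z − mean_m H₊⁽ᵐ⁾‖² − ‖Z − mean_m H₋⁽ᵐ⁾‖²  (may be negative)

and the objective is J = Σₘ L_contrast + β L_consensus with β = 0.001.
Each layer graph is encoded separately (a single-layer multiplex) by one
shared encoder, which is what makes per-graph contrastive terms and the
cross-graph consensus meaningful. Pretraining runs 200 epochs by default
with a plateau-based early abort. Pretraining uses no labels, so in
cross-validation it is run once per seed and shared across folds.

## Pseudo-positive augmentation

A separate two-layer graph convolution estimates class probabilities
P = softmax(Â [Σ_k T_k(L̂) X Θ_k] W) on a single *probability graph* — by
default the symmetrized union of all layers (configurable to any single
layer). T_k is the Chebyshev recurrence (T₀ = I, T₁ = L̂,
T_k = 2 L̂ T_{k−1} − T_{k−2}) on the scaled Laplacian L̂ = 2L/λ_max − I;
K = 2 by default. Only positive labels exist at this stage, so the model
is trained (cross-entropy, 200 epochs) on the labeled positives against an
equal-sized seeded random sample of unlabeled genes as provisional
negatives — the standard positive–unlabeled device.

Candidates are the unlabeled genes provisionally assigned to the positive
class, ranked by prediction entropy H_i = −Σ_c p_ic ln p_ic ascending and
truncated to `retain_count` (default 2·|S₊|). The labeled positives are
then spectrally clustered into two groups under an RBF affinity
κ(q,u) = exp(−‖φ(q)−φ(u)‖²/2σ²), where φ is per-column standardization
fit on the positives and σ defaults to the median pairwise distance. A
candidate i survives if p_{i,+} ≥ θ_p (default 0.8, boundary inclusive)
and its distance to the nearest positive-cluster centroid is at most
mean + std (population) of the positives' own centroid distances (boundary
inclusive). The distance clause can only shrink the candidate set — a
property the tests assert.

## Negative inference by internal contrastive learning

With no trustworthy non-driver list, high-confidence negatives are inferred
with a one-class model trained on the (augmented) positives only. Each
input vector of length f is cut into m = f − k + 1 sliding window pairs
(window of length k, complement of length f − k, order preserved). Dual
two-layer MLP encoders (hidden 64, output 32, unit-normalized) are trained
so a complement identifies its own window among the m candidates of the
same sample (temperature softmax, τ = 0.1, k = 8 by default). The anomaly
score y(x) sums the per-window losses; the top-scoring unlabeled genes —
as many as there are positives after augmentation — become the negative
set. Ties are broken by ascending gene index.

The model runs on the consensus embedding Z by default (raw features are a
config switch). Note the pretext task needs *position-dependent structure*
in the positive class: for i.i.d. features with a flat mean, windows and
complements are independent and nothing can be learned. Z-scored
class-shifted features and learned embeddings have such structure; a flat
white-noise toy does not (the test suite documents this).

## Classifier and objective

A second, separately parameterized encoder (pretraining produces the
consensus embedding only) feeds a linear head,
Ŷ = softmax(H⁽ᴸ⁾ W_cls + b_cls), with the summed cross-entropy over
labeled nodes L_sup = −Σ_{i∈V_L} log Ŷ_{i,y_i}. A consistency regularizer
penalizes per-node gates that stray from the population mean: node gates
are first averaged over all layers and graphs of the classifier encoder,
then L_reg = (1/n)Σᵢ(γ̄_fwd − Γᵢ_fwd)² + (1/n)Σᵢ(γ̄_bwd − Γᵢ_bwd)², which by
complementarity equals twice the population variance of the averaged
forward gates (asserted against a brute-force oracle). The objective is
L_sup + λ L_reg with λ = 0.0003; AdamW, learning rate 0.01, weight decay
0. Early stopping monitors the supervised loss on a stratified 10%
holdout of the labeled nodes (patience 30, max 1000 epochs by default);
the best-validation parameters are restored.

## Cross-validation protocol and leakage

The known positives are split into shuffled k-folds (a single class, so
stratification is vacuous). By default, pseudo-positive augmentation and
negative inference are re-run inside each fold using only the training
positives; test positives are excluded from the pseudo-label candidates
and from the negative pool, so no training-side component ever sees them.
Training and test negatives are drawn from the same ICL ranking
(ratio × |augmented training positives| + ratio × |test positives| genes),
then shuffled before the train/test split so neither side systematically
receives higher-confidence negatives. `paper_mode` instead augments once
globally and folds the fixed labeled set. Per-gene scores are Ŷ_{i,+};
imbalance experiments scale the negative count by the requested
positive:negative ratio in both train and test sets.

## Numerical backbone

All differentiable components run on a small tape-based reverse-mode
autodiff engine over numpy and scipy.sparse written for this package
(`driverplex.nn`): dense/broadcast arithmetic, matmul, products with
constant sparse operators, row gathering with scatter-add gradients,
numerically stable log-sigmoid and log-softmax, dropout, and AdamW.
Gradients are verified against central finite differences in the test
suite. The problem sizes this package targets in its experiments (a few
hundred to a few thousand genes) run comfortably full-batch.

## Synthetic benchmarks

The generator emulates the shapes of the real task: M = 6 layers (3
directed + 3 undirected, mirroring the mix of real interaction resources),
f = 48 features, a small positive class, and three planted, independently
tunable signals —

* **homophily h**: pair probabilities interpolate (t = 2h−1) between the
  exactly class-blind uniform graph at h = 0.5 and a degree-balanced fully
  homophilous graph at h = 1, with the within-class probability scaled per
  class so every node has expected degree d = density·(n−1) at every h.
  Degree therefore carries no class signal at any h — only neighborhood
  *composition* does. Base density defaults to 0.02;
* **direction asymmetry δ**: in directed layers, arcs emitted by drivers
  are scaled by (1+δ) and arcs received by drivers by (1−δ) — drivers act
  as regulatory sources (high out-, low in-degree, as transcription
  factors and kinases do in regulatory and kinase–substrate networks).
  The up- and down-weighting cancel to first order in the symmetrized
  graph, so this class signal lives in edge *orientation* only;
* **feature effect size**: the class-conditional Gaussian feature means
  differ by `effect_size` σ along one fixed random direction, then
  columns are z-scored. Class-conditional Gaussians suffice because the
  pipeline consumes only z-scored continuous features.

A fraction (default 20%) of true drivers is hidden — relabeled unlabeled —
so augmentation and negative inference can be scored against ground truth.
Presets: easy (h=0.9, effect 2.0, δ=0.5), medium (0.7, 1.0, 0.3), hard
(0.5, 0.0, 0.0 — a pure null). Everything is reproducible per seed.

What passing these benchmarks does *not* show: real networks have
heavy-tailed degrees, correlated layers, and feature noise far from
Gaussian; the generator makes no attempt to match degree distributions
(planted-partition layers are Erdős–Rényi-like), and pseudo-label
precision on a clean Gaussian mixture is an upper bound on what noisy
omics features allow.

## Desk-scale experiment sizes

The synthetic experiments and the acceptance script use a scaled-down
configuration chosen as this package's benchmark setting
(`driverplex.pipeline.desk_config`): graphs of 200 genes (400 for the null
control) with 30 visible positives, a 16-unit 2-layer encoder, 30
pretraining epochs, 40 ICL epochs, ICL window 4 on the consensus
embedding, and 150 training epochs with patience 15. At these sizes one
full pipeline run takes seconds and the complete experiment battery
minutes, while every qualitative property of the full-size configuration
is preserved.

## Known limitations

* On the easy benchmark preset the symmetric signal (homophilous layers
  plus 2σ features) saturates desk-scale accuracy, so the directionality
  ablation contrast — a ~1–2% effect in realistic regimes — is not
  resolvable there: both the full and the symmetrized model sit at the
  ceiling, and the paired comparison across seeds reduces to ties and
  noise. The ablation machinery itself is exact (symmetrize-then-encode
  equals the ablation flag, bitwise) and the δ = 0 control behaves as
  expected.
* Directional information enters representations only through the scalar
  per-node gates; with uninformative neighbor features there is nothing
  class-relevant to aggregate, so a *pure* orientation signal (no feature,
  no homophily signal) is not learnable by design.
* The equal-sized provisional-negative sample for the probability model is
  the one genuinely arbitrary choice in the augmentation stage; with very
  high contamination of the unlabeled pool it would bias θ_p calibration.
* Networks are combined by unweighted averaging; no per-layer learned
  weighting is attempted.
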