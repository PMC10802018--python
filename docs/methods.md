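# Methods

## Problem setting

Disease-subtype classification from multi-omics data is chronically
label-starved: molecular profiles (mRNA expression, DNA methylation,
microRNA expression) are measured for every patient, but subtype labels —
which require expert annotation or long clinical follow-up — exist for only
a subset. `mosegcn` implements a transductive, semi-supervised pipeline
that uses every patient, labeled or not, in all three of its stages:

1. **Latent feature learning.** The per-omics matrices are concatenated
   into X ∈ R^(N×P) and compressed by an autoencoder whose encoder contains
   a multi-head scaled dot-product self-attention block. Only the encoder
   half is kept; its output H ∈ R^(N×K) is the feature matrix the
   classifier consumes.
2. **Patient graph construction.** Each omics block independently yields a
   patient-similarity network via a scaled exponential kernel on Euclidean
   distances with a locally adaptive bandwidth; similarity network fusion
   (cross-diffusion) merges the per-omics networks into one fused network,
   which is pruned to each node's strongest edges and used as the GCN
   adjacency.
3. **Mean-teacher GCN classification.** A two-layer graph convolutional
   network (student) is trained with cross-entropy on labeled nodes plus a
   consistency penalty between a dropout-perturbed student forward pass and
   the predictions of a teacher network whose weights are the exponential
   moving average of the student's. Unlabeled nodes contribute gradients
   through the consistency term. Evaluation uses the teacher.

A sensitivity analysis of the trained teacher ranks input features
(importance = feature standard deviation × aggregate first-layer weight
magnitude) as candidate biomarkers, extracted per omics on a fixed epoch
schedule and consolidated across checkpoints.

## Model components and their assumptions

### Attention autoencoder

Architecture: dense layer P→K with ReLU → multi-head self-attention block
(h heads, per-head width K/h, output projection W^o, residual connection,
row-wise layer normalisation) → position-wise feedforward block (width 2K,
residual, layer norm) → dense decoder K→P. Training minimises the mean
squared reconstruction error over all entries with Adam; autoencoding is
unsupervised, so all samples (labeled and unlabeled) are used.

The attention axis is the **sample** axis: H left-multiplies the projection
matrices, so the N patients are the attention positions and the attention
matrix is N×N, row-stochastic. This captures patient–patient dependence in
the latent space. An alternative `attention_axis="features"` mode splits
each patient's latent vector into equal-width tokens and attends across
tokens per patient; it is provided for exploration but is not the default
and is substantially slower (a per-sample loop).

Defaults: K = 200, h = 4 heads, feedforward width 2K, learning rate 1e-3,
200 epochs. The latent width, depth, optimizer and epochs are modelling
choices (no single published value governs them); h = 4 reflects the
head-count at which classification quality peaks in a sweep over
{2, 4, 8, 16}. Layer normalisation (not batch norm) is used, the standard
choice for attention blocks.

### Similarity network fusion

Per-omics affinity: W(i,j) = exp(−D(i,j)² / (μ·ε_ij)), D Euclidean,
ε_ij = (mean distance of i to its K nearest neighbours + same for j +
D(i,j))/3. Defaults K = 30 neighbours, μ = 0.5. Coincident samples
(ε = 0) receive affinity 1 by the exp(0) convention.

Fusion follows the cross-diffusion recurrence: full kernels P_v (diagonal
1/2, off-diagonal rows normalised to sum 1/2) are updated T = 20 times via
P_v ← S_v · mean(P_w, w≠v) · S_vᵀ with S_v the row-normalised KNN-truncated
kernel (self excluded), re-symmetrised and renormalised each iteration; the
fused network is the mean of the final P_v. Weak edges are then pruned:
each node keeps its K strongest edges, union-symmetrised (an edge survives
if either endpoint retains it). Note that cross-diffusion genuinely
diffuses: fusing two identical networks returns the T-step diffusion of
that network, not the network itself — the invariant tests therefore check
the implementation against an independently coded reference recurrence
rather than asserting a literal fixed point.

SNF runs on the preprocessed per-omics matrices by default (each omics
contributes its own patient geometry); `snf_input="latent"` slices the
encoder output instead.

### Mean-teacher GCN

Normalised adjacency Â = D̃^(−1/2)(A+I)D̃^(−1/2) with D̃ the degree of
A+I; any diagonal of the incoming A is discarded first so self-loops are
added exactly once. Forward pass: softmax(Â·ReLU(Â X Θ⁽¹⁾)·Θ⁽²⁾) — two
layers, no bias terms, matching the convolution rule exactly. The student's
perturbation is a single dropout layer (rate 0.5) on the hidden
representation. Losses:

- supervised: mean over labeled nodes of −Σ_c y_c log p_c (probabilities
  clamped at 1e-12);
- consistency: mean squared difference between teacher and
  perturbed-student probability matrices over **all** nodes, with equal
  per-node weight (a KL variant is available behind
  `consistency="kl"`);
- total: CE + λ·consistency, with λ ramped from 0 to λ_max = 1 over the
  first 30% of epochs by the sigmoid-shaped schedule exp(−5(1−t/T_ramp)²),
  and teacher weights updated after every step by
  Θ_t ← αΘ_t + (1−α)Θ_s with α = 0.99.

The EMA coefficient and λ schedule follow the mean-teacher convention; the
source SEGCN defaults are not published, so these are reconstructions and
both are overridable.

Training is transductive: test nodes are present in the graph and in the
consistency term but their labels never enter the supervised loss (the
evaluation protocol masks them to the unlabeled sentinel before fitting).

Two numerical choices deserve note, both forced by observed failures:

- **Learning rate.** With no bias terms, Adam at 1e-2 reliably drives the
  ReLU hidden layer into an all-dead state (logits 0, CE pinned at log C,
  zero gradient) on fused-network inputs. The default is 1e-3, which is
  stable across the test suite.
- **Edge-mass rescaling.** The fused kernel's off-diagonal row mass is
  ≤ 1/2 by construction and far smaller after pruning (~0.1), while the GCN
  normalisation adds a unit self-loop; unrescaled, Â is numerically close
  to the identity (diagonal ≈ 0.93) and no label information propagates.
  The pipeline therefore rescales the pruned network so the mean
  off-diagonal row mass is 1 before normalisation. This is a pipeline
  choice layered on top of `normalize_adjacency`, which itself implements
  the textbook formula unchanged.

### Biomarker sensitivity analysis

importance_i = σ_i · Σ_j |W_ij|, with σ_i the (population) standard
deviation of preprocessed input feature i over all samples and W the
teacher's first-layer weights. When the GCN consumes the encoder's latent
features, latent importances Σ_j |Θ⁽¹⁾_kj| are chained to raw features
through |W_enc|: importance_i = σ_i · Σ_k |W_enc[i,k]| · Σ_j |Θ⁽¹⁾_kj|.
Absolute-value aggregation is the sensitivity-analysis standard; sum of
squares and max variants are available. Ranking is per omics block; the
top-30 lists extracted every 400 epochs (and at the final epoch) are
consolidated by (occurrence count desc, mean within-checkpoint rank asc).

## Preprocessing

Per omics block, in order: restrict to samples common to all blocks
(sorted identifier order, for reproducibility across input file order);
drop zero-mean features and constant features (the latter so min-max
scaling never divides by zero); keep the top fraction of features by
variance (ceil(fraction·p), ties to the earlier column; default fraction
1.0, i.e. pass-through, with 0.25 the conventional choice for large
expression panels and pass-through for small microRNA panels); min-max
scale each feature to [0,1] over **all** samples. Computing scaling
statistics before the train/test split is deliberate: the model is
transductive and sees every node during training, so the alternative would
misrepresent how the method is deployed. It is a known leakage trade-off
inherent to the setting. Missing values are rejected at load time.

## Synthetic data generator

The generator emulates the study design: m aligned omics blocks over the
same patients, C classes, a small set of informative features per block,
nuisance features, Gaussian noise, and a stratified labeled fraction.
Informative-feature class means sit at the vertices of a regular simplex in
the informative subspace, scaled so every pair of class means is exactly
effect_size·noise_sd apart, then randomly rotated within that subspace so
no feature direction is privileged. Nuisance features are
class-independent N(0, noise_sd²). Labels are revealed for a stratified
fraction of samples (error if any class would have zero labeled samples).
Everything is a deterministic function of the seed.

What the generator does **not** emulate: platform-specific marginals
(methylation beta values in [0,1], overdispersed counts for RNA-seq),
heavy tails, batch effects, missingness, correlated noise between features,
or disagreeing cluster structures across omics. Passing tests therefore
demonstrate that the pipeline recovers planted Gaussian cluster structure
and planted markers under honest label scarcity — not that it matches any
particular performance level on real cohorts.

## Study conditions and problem sizes used in tests

The synthetic study conditions are: N = 300 patients, C = 3 classes,
three omics blocks of 100/80/60 features, 5 informative features per
block, noise sd 1. The end-to-end check uses effect size 4 with 30%
labeled (5 repeated 7:3 splits); the semi-supervised comparison uses
effect size 3 with 10% labeled over 10 generator seeds; the chance-level
control uses effect size 0; biomarker recovery uses effect size 4 over 10
seeds. Model settings for these runs are latent K = 64 with 800 encoder
epochs (lr 5e-3) and a 64-unit hidden GCN layer trained 1000 epochs
(800 for biomarker runs so the 400-epoch checkpoint schedule yields two
checkpoints plus the final one) — sizes at which the latent representation
is cleanly separable (linear-probe accuracy ≈ 0.97–1.0 at effect 4) while a
full experiment stays in the tens of seconds.

## Evaluation protocol

Stratified 7:3 train/test splits of the *labeled* samples, repeated 30
times by default (the stochastic test conditions above use fewer, as
noted); per-repeat metrics are averaged and reported with their standard
deviation. Binary tasks report accuracy, precision, recall, F1 and AUC;
multiclass tasks report accuracy, macro precision/recall, weighted and
macro F1 (AUC is binary-only). Because the encoder and the fused network
are unsupervised, they are shared across repeats by default
(`cache_representation=True`); per-repeat retraining is available for
strict protocol parity.

## Known limitations

- The sample-axis attention makes each latent row a mixture over patients;
  at small latent widths or short training this measurably degrades the
  latent representation before it recovers with capacity/epochs. The
  encoder must be trained long enough (watch the reconstruction trace).
- The GCN has no bias terms (faithful to the convolution rule), which
  makes optimisation touchier than standard GCN implementations; see the
  learning-rate note above.
- Min-max statistics over all samples leak test-feature ranges by design
  (transductive setting).
- The feature-axis attention mode is a per-sample loop; use it only for
  small N.
- `single_omics_ablation` with one block bypasses fusion entirely (the
  block's full kernel is the graph); its results are not comparable to
  fused runs when block feature scales differ grossly.
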