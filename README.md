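# mosegcn

Semi-supervised disease-subtype classification from multi-omics data.

Molecular subtyping studies routinely profile every patient on several
omics layers (mRNA expression, DNA methylation, microRNA expression) but
obtain subtype labels for only a fraction of them. `mosegcn` is aimed at
computational biologists who want to classify *all* patients in such a
cohort — using the unlabeled ones as first-class training signal — and to
rank the molecular features that drive the classification.

## Method

The pipeline has three stages plus a feature-ranking step:

1. **Attention autoencoder.** The concatenated omics matrix
   X ∈ R^(N×P) is encoded to a latent representation
   H = Encoder(X, θ_e) ∈ R^(N×K) by a dense layer followed by a multi-head
   scaled dot-product self-attention block,
   Head_i = softmax(Q_i K_iᵀ / √d_K) V_i with Q_i = H W_i^Q etc., and
   MultiHead(Q,K,V) = Concat(head_1…head_h) W^o, with residual connections
   and layer normalisation. Training minimises ‖X − X̃‖²_F through a mirror
   decoder; only the encoder is kept.
2. **Similarity network fusion.** Each omics block yields a patient
   affinity network W(i,j) = exp(−D(i,j)²/(μ·ε_ij)) with a locally adaptive
   bandwidth (K = 30 neighbours, μ = 0.5); cross-diffusion
   P_v ← S_v · mean(P_w, w≠v) · S_vᵀ (T = 20 iterations) fuses them into a
   single patient graph, and weak edges are pruned.
3. **Mean-teacher GCN.** A two-layer graph convolutional network
   Z = Â · ReLU(Â X Θ⁽¹⁾) · Θ⁽²⁾ with Â = D̃^(−1/2)(A+I)D̃^(−1/2) is
   trained as a student with cross-entropy on labeled nodes plus a
   consistency loss between a dropout-perturbed student pass and a teacher
   whose weights track the student by exponential moving average
   (Θ_t ← αΘ_t + (1−α)Θ_s, α = 0.99). Unlabeled nodes contribute gradients
   through the consistency term; the teacher makes the final predictions.

**Biomarkers.** Features are ranked by sensitivity,
importance_i = σ_i · Σ_j |W_ij| (feature standard deviation × aggregate
first-layer weight magnitude of the teacher), per omics block; top-30
lists extracted every 400 epochs are consolidated across checkpoints.

See `docs/methods.md` for assumptions, defaults, numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Worked example

Generate a synthetic three-omics cohort with planted subtype structure
(150 patients, 3 subtypes, 5 informative features per omics at effect size
4, 30% of patients labeled) and run the full pipeline with 5 repeated 7:3
splits:

```python
from mosegcn import SyntheticSpec, generate_multiomics, PipelineConfig, run_experiment

spec = SyntheticSpec(
    n_samples=150, n_classes=3, feature_counts=(60, 40, 30),
    informative_per_omics=5, effect_size=4.0, labeled_fraction=0.3, seed=7,
)
dataset, truth = generate_multiomics(spec)

config = PipelineConfig(
    n_repeats=5, seed=7,
    encoder={"latent_dim": 64, "epochs": 800, "learning_rate": 5e-3},
    segcn={"epochs": 1000, "hidden_dim": 64},
    run_biomarkers=True, biomarker_checkpoint_every=400,
)
result = run_experiment(dataset, config)
print(result.summary.round(3))
print(result.biomarkers.tables["omics1"].head(5).round(3).to_string(index=False))
```

Output:

```
        acc  precision  recall  f1_weighted  f1_macro
mean  0.986      0.989   0.987        0.986     0.987
std   0.032      0.025   0.030        0.032     0.030
 feature_id  occurrences  mean_rank  mean_importance
omics1_f002            3      1.000           13.962
omics1_f042            3      2.000           11.092
omics1_f055            3      3.667           11.020
omics1_f009            3      4.333           10.986
omics1_f017            3      4.333           10.975
```

The teacher classifies the held-out 30% of labeled patients with 98.6%
mean accuracy across the five splits (±3.2% sd), and the consolidated
biomarker table surfaces the planted informative features: of the five
features actually planted in `omics1`
(`f002, f017, f023, f036, f042`), three sit in the top five of the ranking
(`f002`, `f042`, `f017`), each recurring in all three checkpoints.

## Command line

```sh
mosegcn simulate --config spec.yaml --out data/        # synthetic cohort as CSVs
mosegcn run --omics mrna.csv --omics meth.csv --omics mirna.csv \
            --labels labels.csv --out results/          # full pipeline
mosegcn biomarkers --dataset data/ --out markers.tsv    # marker report only
```

Omics files are CSV/TSV matrices (first row/column identifiers; use
`rows-are-features` orientation via the library API if needed); labels are
a two-column `sample_id,label` file. Samples missing from the label file
are kept as unlabeled nodes.

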