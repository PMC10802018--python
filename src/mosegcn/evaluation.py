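"""Experiment protocol: repeated stratified splits, metrics, full pipeline.

The evaluation protocol is transductive: labeled samples are split 7:3 into
train and test, 30 times; within each repeat the test samples' labels are
masked (they join the unlabeled pool for the consistency term) and the
teacher's predictions on the test mask are scored. Binary tasks report
ACC / F1 / AUC / precision / recall; multiclass tasks report ACC /
F1_weighted / F1_macro / precision / recall (macro averaging).

``run_experiment`` wires the whole method together per repeat: encoder
training on the concatenated omics, similarity network fusion into the GCN
adjacency, mean-teacher fitting, teacher prediction, and (optionally)
sensitivity-based biomarker extraction on the final repeat's teacher.
Because the encoder and the fused network are unsupervised, they may be
computed once per dataset and shared across repeats (``cache_representation``,
on by default); per-repeat re-training is available for strict protocol
parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedShuffleSplit

from . import biomarker as bm
from . import segcn, snf
from .encoder import EncoderConfig, train_encoder
from .omics_data import UNLABELED, MultiOmicsDataset, concat_features, preprocess
from .segcn import SEGCNConfig

__all__ = [
    "SplitPlan",
    "PipelineConfig",
    "ExperimentResult",
    "make_splits",
    "compute_metrics",
    "build_representation",
    "run_experiment",
    "single_omics_ablation",
]


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/test partitions of the labeled samples."""

    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    n_repeats: int
    train_fraction: float
    seed: int


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, with published defaults.

    ``encoder`` and ``segcn`` hold keyword overrides applied on top of the
    module defaults (latent K = 200, 200 encoder epochs, 4 heads; GCN
    hidden 64, 1000 epochs, dropout 0.5, EMA 0.99).
    """

    n_repeats: int = 30
    train_fraction: float = 0.7
    seed: int = 0
    apply_preprocess: bool = True
    variance_keep_fraction: float = 1.0
    encoder: dict = field(default_factory=dict)
    segcn: dict = field(default_factory=dict)
    snf_k_neighbors: int = 30
    snf_mu: float = 0.5
    snf_iterations: int = 20
    prune_rule: str = "top-k"
    snf_input: str = "preprocessed"  # "preprocessed" | "latent"
    gcn_features: str = "latent"  # "latent" | "raw"
    cache_representation: bool = True
    run_biomarkers: bool = False
    biomarker_top_k: int = 30
    biomarker_checkpoint_every: int = 400

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ExperimentResult:
    """Per-repeat metrics, their mean/sd summary, and optional biomarkers."""

    per_repeat: pd.DataFrame
    summary: pd.DataFrame
    biomarkers: bm.BiomarkerReport | None = None
    predictions: dict | None = None


# -------------------------------------------------------------------- splits
def make_splits(
    labels, n_repeats: int = 30, train_fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Stratified repeated 7:3 partitions of the labeled samples."""
    labeled = labels.labeled_mask
    ids = np.array(labels.sample_ids)[labeled]
    y = labels.y[labeled]
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        few = classes[counts < 2].tolist()
        raise ValueError(f"classes {few} have fewer than 2 labeled samples; cannot stratify")
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    splits = []
    for train_idx, test_idx in sss.split(ids, y):
        splits.append((tuple(ids[train_idx]), tuple(ids[test_idx])))
    return SplitPlan(
        splits=tuple(splits),
        n_repeats=n_repeats,
        train_fraction=train_fraction,
        seed=seed,
    )


# ------------------------------------------------------------------- metrics
def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray | None = None,
    task: str = "multiclass",
) -> dict[str, float]:
    """One row of the metric report; see module docstring for definitions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    row: dict[str, float] = {"acc": float(accuracy_score(y_true, y_pred))}
    if task == "binary":
        row["precision"] = float(precision_score(y_true, y_pred, zero_division=0))
        row["recall"] = float(recall_score(y_true, y_pred, zero_division=0))
        row["f1"] = float(f1_score(y_true, y_pred, zero_division=0))
        if probs is not None and np.unique(y_true).size == 2:
            row["auc"] = float(roc_auc_score(y_true, probs[:, 1]))
        else:
            row["auc"] = float("nan")
    elif task == "multiclass":
        row["precision"] = float(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        row["recall"] = float(recall_score(y_true, y_pred, average="macro", zero_division=0))
        row["f1_weighted"] = float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        )
        row["f1_macro"] = float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    else:
        raise ValueError(f"unknown task {task!r}")
    return row


# ------------------------------------------------------------ representation
@dataclass
class Representation:
    """Shared unsupervised products of one dataset: features + graph."""

    dataset: MultiOmicsDataset
    X: np.ndarray
    block_widths: tuple[int, ...]
    H: np.ndarray
    encoder_weights: object
    encoder_config: EncoderConfig
    A_hat: segcn.NormalizedAdjacency
    features: np.ndarray  # what the GCN consumes (H or X)


def build_representation(dataset: MultiOmicsDataset, config: PipelineConfig) -> Representation:
    """Preprocess, train the encoder, fuse the similarity networks."""
    if config.apply_preprocess:
        dataset = preprocess(
            list(dataset.omics), dataset.labels, config.variance_keep_fraction
        )
    X, widths = concat_features(dataset)

    enc_kwargs = {"input_dim": X.shape[1], "seed": config.seed, **config.encoder}
    enc_config = EncoderConfig(**enc_kwargs)
    weights, latent, _ = train_encoder(X, enc_config, dataset.sample_ids)
    H = latent.H

    if config.snf_input == "latent":
        # split H into contiguous slices proportional to the block widths
        cuts = np.round(np.cumsum(widths) / sum(widths) * H.shape[1]).astype(int)[:-1]
        views = np.split(H, cuts, axis=1)
    else:
        views = [block.values for block in dataset.omics]

    nets = [
        snf.affinity_kernel(
            snf.pairwise_distance(V),
            k_neighbors=config.snf_k_neighbors,
            mu=config.snf_mu,
            name=block.name,
        )
        for V, block in zip(views, dataset.omics)
    ]
    if len(nets) == 1:
        P = snf.full_kernel(nets[0].W)
        fused = snf.FusedNetwork(matrix=(P + P.T) / 2.0, iterations=0)
    else:
        fused = snf.snf_fuse(nets, t_iterations=config.snf_iterations)
    pruned = snf.prune_weak_edges(
        fused, rule=config.prune_rule, k_neighbors=config.snf_k_neighbors
    )
    # Rescale edge weights so the mean off-diagonal row mass is 1: the fused
    # kernel's rows carry only ~1/2 total off-diagonal mass before pruning and
    # far less after, so without rescaling the unit self-loop added by the
    # GCN normalisation would swamp the graph and suppress propagation.
    A = pruned.matrix.copy()
    np.fill_diagonal(A, 0.0)
    mass = A.sum(axis=1).mean()
    if mass > 0:
        A /= mass
    A_hat = segcn.normalize_adjacency(A, provenance=f"snf:{config.prune_rule}")

    features = H if config.gcn_features == "latent" else X
    return Representation(
        dataset=dataset,
        X=X,
        block_widths=widths,
        H=H,
        encoder_weights=weights,
        encoder_config=enc_config,
        A_hat=A_hat,
        features=features,
    )


# ---------------------------------------------------------------- experiment
def _biomarker_checkpoints(rep: Representation, config: PipelineConfig, state_epochs):
    """Turn teacher first-layer snapshots into consolidated biomarkers."""
    dataset = rep.dataset
    feature_ids = [f for block in dataset.omics for f in block.feature_ids]
    names = [block.name for block in dataset.omics]
    checkpoints = []
    for epoch, theta1 in state_epochs:
        if config.gcn_features == "latent":
            latent_rowsums = np.abs(theta1).sum(axis=1)
            imp = bm.latent_importance_to_raw(
                latent_rowsums, rep.encoder_weights.W_enc.value, rep.X
            )
            # wrap the chained raw importances in a table directly
            scores = {}
            offset = 0
            for name, width in zip(names, rep.block_widths):
                scores[name] = pd.Series(
                    imp[offset : offset + width],
                    index=feature_ids[offset : offset + width],
                )
                offset += width
            table = bm.ImportanceTable(scores=scores, epoch=epoch)
        else:
            table = bm.sensitivity_importance(
                rep.X, theta1, feature_ids, list(rep.block_widths), names, epoch=epoch
            )
        checkpoints.append((epoch, table, bm.extract_top_k(table, config.biomarker_top_k)))
    return bm.consolidate(checkpoints, k=config.biomarker_top_k)


def run_experiment(
    dataset: MultiOmicsDataset, config: PipelineConfig
) -> ExperimentResult:
    """Full protocol: repeated splits over one dataset, averaged metrics."""
    labels = dataset.labels
    task = "binary" if labels.n_classes == 2 else "multiclass"
    plan = make_splits(labels, config.n_repeats, config.train_fraction, config.seed)

    rep_cache = build_representation(dataset, config) if config.cache_representation else None
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_repeats)]

    rows = []
    predictions: dict = {}
    biomarkers = None
    for r, (train_ids, test_ids) in enumerate(plan.splits):
        rep = rep_cache if rep_cache is not None else build_representation(
            dataset, replace(config, seed=repeat_seeds[r])
        )
        ds = rep.dataset
        pos = {s: i for i, s in enumerate(ds.sample_ids)}
        train_idx = np.array([pos[s] for s in train_ids])
        test_idx = np.array([pos[s] for s in test_ids])

        y_masked = np.full(ds.n_samples, UNLABELED, dtype=np.int64)
        y_masked[train_idx] = ds.labels.y[train_idx]

        seg_kwargs = {"seed": repeat_seeds[r], **config.segcn}
        seg_config = SEGCNConfig(**seg_kwargs)

        snapshots: list[tuple[int, np.ndarray]] = []
        is_last = r == len(plan.splits) - 1
        hook = None
        every = None
        if config.run_biomarkers and is_last:
            every = config.biomarker_checkpoint_every

            def hook(epoch, state, _snap=snapshots):
                _snap.append((epoch, state.teacher.theta1.value.copy()))

        state, log = segcn.fit(
            rep.features, rep.A_hat, y_masked, labels.n_classes, seg_config,
            checkpoint_every=every, on_checkpoint=hook,
        )
        pred, probs = segcn.predict(state, rep.A_hat, rep.features)
        y_test = ds.labels.y[test_idx]
        row = compute_metrics(y_test, pred[test_idx], probs[test_idx], task)
        row["repeat"] = r
        rows.append(row)
        predictions[r] = {
            "test_ids": test_ids,
            "y_true": y_test,
            "y_pred": pred[test_idx],
            "log": log,
        }
        if config.run_biomarkers and is_last and snapshots:
            biomarkers = _biomarker_checkpoints(rep, config, snapshots)

    per_repeat = pd.DataFrame(rows).set_index("repeat")
    summary = per_repeat.agg(["mean", "std"])
    return ExperimentResult(
        per_repeat=per_repeat, summary=summary, biomarkers=biomarkers, predictions=predictions
    )


def single_omics_ablation(
    dataset: MultiOmicsDataset, config: PipelineConfig
) -> dict[str, ExperimentResult]:
    """Run the pipeline per single omics block and on all blocks together.

    With one block there is nothing to fuse: the block's affinity kernel
    (full-kernel normalised) is used directly as the graph.
    """
    if len(dataset.omics) < 2:
        raise ValueError("ablation needs a multi-omics dataset")
    results: dict[str, ExperimentResult] = {}
    for block in dataset.omics:
        sub = MultiOmicsDataset(omics=(block,), labels=dataset.labels)
        results[block.name] = run_experiment(sub, config)
    results["all"] = run_experiment(dataset, config)
    return results
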