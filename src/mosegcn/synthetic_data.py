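"""Synthetic aligned multi-omics datasets with known class structure.

The generator emulates the study design the pipeline targets: several
aligned omics blocks measured on the same patients, a small set of
class-separating ("informative") features per block, many nuisance
features, Gaussian measurement noise, and labels revealed for only a
stratified fraction of samples. Class means for the informative features
sit at the vertices of a regular simplex in the informative subspace
(pairwise distance ``effect_size * noise_sd``), randomly rotated, so no
class pair is privileged. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ortho_group

from .omics_data import UNLABELED, LabelSet, MultiOmicsDataset, OmicsMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_multiomics"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters for one synthetic dataset."""

    n_samples: int = 300
    n_classes: int = 3
    feature_counts: tuple[int, ...] = (100, 80, 60)
    informative_per_omics: int = 5
    effect_size: float = 4.0
    noise_sd: float = 1.0
    labeled_fraction: float = 0.3
    seed: int = 0
    omics_names: tuple[str, ...] = field(default=())
    class_proportions: tuple[float, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "feature_counts", tuple(self.feature_counts))
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.informative_per_omics > min(self.feature_counts):
            raise ValueError("informative_per_omics exceeds a block's feature count")
        if self.informative_per_omics < self.n_classes - 1:
            raise ValueError(
                "informative_per_omics must be >= n_classes - 1 so that "
                "equidistant class means fit in the informative subspace"
            )
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.omics_names:
            object.__setattr__(
                self,
                "omics_names",
                tuple(f"omics{i + 1}" for i in range(len(self.feature_counts))),
            )
        if not self.class_proportions:
            object.__setattr__(
                self,
                "class_proportions",
                tuple(1.0 / self.n_classes for _ in range(self.n_classes)),
            )
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth the generator plants: which features/labels are real."""

    informative_features: dict[str, tuple[str, ...]]
    true_classes: np.ndarray
    labeled_sample_ids: tuple[str, ...]


def _simplex_means(C: int, dim: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """C equidistant class-mean vectors in R^dim with pairwise distance ``separation``."""
    # vertices of the regular simplex: centred standard basis of R^C has
    # pairwise distance sqrt(2); project to C-1 dims and rescale
    V = np.eye(C) - 1.0 / C
    # orthonormal basis of the (C-1)-dim affine hull
    q, _ = np.linalg.qr(V.T)
    coords = V @ q[:, : C - 1]
    coords *= separation / np.sqrt(2.0)
    means = np.zeros((C, dim))
    means[:, : C - 1] = coords
    if dim > 1:
        rot = ortho_group.rvs(dim, random_state=rng)
        means = means @ rot
    return means


def generate_multiomics(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Draw one dataset and its ground truth from the generative model."""
    rng = np.random.default_rng(spec.seed)
    N, C = spec.n_samples, spec.n_classes

    counts = np.floor(np.asarray(spec.class_proportions) * N).astype(int)
    counts[: N - counts.sum()] += 1  # distribute the rounding remainder
    true_classes = np.repeat(np.arange(C), counts)
    rng.shuffle(true_classes)

    sample_ids = tuple(f"s{i + 1:04d}" for i in range(N))
    blocks = []
    informative: dict[str, tuple[str, ...]] = {}
    for name, p in zip(spec.omics_names, spec.feature_counts):
        k = spec.informative_per_omics
        means = _simplex_means(C, k, spec.effect_size * spec.noise_sd, rng)
        values = rng.normal(0.0, spec.noise_sd, size=(N, p))
        values[:, :k] += means[true_classes]
        # shuffle columns so informative features are not always the first k
        perm = rng.permutation(p)
        values = values[:, perm]
        feature_ids = tuple(f"{name}_f{j + 1:03d}" for j in range(p))
        inv = np.argsort(perm)
        informative[name] = tuple(feature_ids[inv[j]] for j in range(k))
        blocks.append(
            OmicsMatrix(name=name, values=values, sample_ids=sample_ids, feature_ids=feature_ids)
        )

    y = np.full(N, UNLABELED, dtype=np.int64)
    labeled_ids = []
    for c in range(C):
        members = np.flatnonzero(true_classes == c)
        n_lab = int(round(spec.labeled_fraction * len(members)))
        if n_lab == 0:
            raise ValueError(
                f"labeled_fraction {spec.labeled_fraction} leaves class {c} "
                "with zero labeled samples; stratification impossible"
            )
        chosen = rng.choice(members, size=n_lab, replace=False)
        y[chosen] = c
        labeled_ids.extend(sample_ids[i] for i in np.sort(chosen))

    labels = LabelSet(
        sample_ids=sample_ids,
        y=y,
        class_names=tuple(f"class{c}" for c in range(C)),
    )
    dataset = MultiOmicsDataset(omics=tuple(blocks), labels=labels)
    truth = SyntheticTruth(
        informative_features=informative,
        true_classes=true_classes,
        labeled_sample_ids=tuple(sorted(labeled_ids)),
    )
    return dataset, truth
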