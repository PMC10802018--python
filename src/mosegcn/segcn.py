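"""Self-ensembling GCN: mean-teacher semi-supervised node classification.

The fused patient network is the graph; every patient (labeled or not) is a
node carrying its latent feature vector. A two-layer graph convolutional
network — Z = A_hat * act(A_hat X Th1) Th2 with the symmetrically
normalised adjacency A_hat = D~^(-1/2) (A + I) D~^(-1/2) — is trained as a
student, while a teacher holds the exponential moving average of the
student's weights. The loss couples cross-entropy on labeled nodes with a
consistency penalty between the teacher's predictions and the student's
predictions under dropout perturbation, computed on *all* nodes, so
unlabeled patients contribute gradients. Evaluation uses the teacher.

Training is transductive: test nodes sit in the graph and in the
consistency term, but their labels never enter the supervised loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .omics_data import UNLABELED

__all__ = [
    "SEGCNConfig",
    "NormalizedAdjacency",
    "GCNParams",
    "TeacherStudentState",
    "normalize_adjacency",
    "gcn_forward",
    "supervised_ce_loss",
    "consistency_loss",
    "total_loss",
    "ema_update",
    "consistency_ramp",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class SEGCNConfig:
    """Mean-teacher GCN hyperparameters.

    The EMA coefficient and the consistency-weight schedule follow the
    mean-teacher convention: alpha = 0.99 and lambda ramped from 0 to
    ``lambda_max`` by exp(-5 (1 - t/T_ramp)^2) over the first
    ``ramp_fraction`` of epochs.
    """

    hidden_dim: int = 64
    dropout: float = 0.5
    alpha_ema: float = 0.99
    lambda_max: float = 1.0
    ramp_fraction: float = 0.3
    consistency: str = "mse"  # "mse" | "kl"
    learning_rate: float = 1e-3
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha_ema <= 1.0:
            raise ValueError("alpha_ema must be in [0, 1]")
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be >= 0")
        if self.consistency not in {"mse", "kl"}:
            raise ValueError(f"unknown consistency {self.consistency!r}")


@dataclass(frozen=True)
class NormalizedAdjacency:
    """A_hat = D~^(-1/2) (A + I) D~^(-1/2); symmetric, entries in [0, 1]."""

    matrix: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", M)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GCNParams:
    """Two-layer GCN weights (the layer count is fixed at two)."""

    theta1: Tensor
    theta2: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.theta1, self.theta2]

    def detached_copy(self) -> "GCNParams":
        return GCNParams(
            theta1=Tensor(self.theta1.value.copy()),
            theta2=Tensor(self.theta2.value.copy()),
        )


@dataclass
class TeacherStudentState:
    """Paired student/teacher parameters plus the EMA and loss settings."""

    student: GCNParams
    teacher: GCNParams
    alpha_ema: float
    lambda_weight: float
    dropout: float = 0.5
    step: int = 0


# ----------------------------------------------------------------- adjacency
def normalize_adjacency(A: np.ndarray, provenance: str = "") -> NormalizedAdjacency:
    """Symmetric GCN normalisation with self-loops added exactly once.

    Any existing diagonal of A is discarded before the identity is added,
    so feeding a pruned fused network (which keeps its diagonal) does not
    double-count self-similarity.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(A - A.T).max() > 1e-8:
        raise ValueError("adjacency must be symmetric within 1e-8")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    A_tilde = A.copy()
    np.fill_diagonal(A_tilde, 0.0)
    A_tilde += np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    A_hat = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(matrix=A_hat, provenance=provenance)


# ------------------------------------------------------------------- forward
def _forward_t(
    A_hat: np.ndarray,
    X: Tensor,
    params: GCNParams,
    perturb: bool,
    dropout: float,
    rng: np.random.Generator | None,
    activation: str = "relu",
) -> Tensor:
    A_t = Tensor(A_hat)
    hidden = A_t @ (X @ params.theta1)
    if activation == "relu":
        hidden = hidden.relu()
    if perturb:
        if rng is None:
            raise ValueError("perturbed forward pass needs an rng for the dropout mask")
        hidden = hidden.dropout(dropout, rng)
    logits = A_t @ (hidden @ params.theta2)
    if not np.isfinite(logits.value).all():
        raise FloatingPointError("non-finite GCN logits")
    return logits.softmax_rows()


def gcn_forward(
    A_hat: NormalizedAdjacency | np.ndarray,
    X: np.ndarray,
    params: GCNParams,
    perturb: bool = False,
    dropout: float = 0.5,
    rng: np.random.Generator | None = None,
    activation: str = "relu",
) -> np.ndarray:
    """Class-probability matrix softmax(A_hat act(A_hat X Th1) Th2)."""
    M = A_hat.matrix if isinstance(A_hat, NormalizedAdjacency) else np.asarray(A_hat)
    return _forward_t(
        M, Tensor(np.asarray(X, dtype=np.float64)), params, perturb, dropout, rng, activation
    ).value


# -------------------------------------------------------------------- losses
_EPS = 1e-12


def supervised_ce_loss(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean over labeled nodes of -sum_c y_c log p_c (probabilities clamped)."""
    probs = np.asarray(probs, dtype=np.float64)
    y_onehot = np.asarray(y_onehot, dtype=np.float64)
    if probs.shape != y_onehot.shape:
        raise ValueError("probs and one-hot labels must share a shape")
    return float(-(y_onehot * np.log(np.maximum(probs, _EPS))).sum(axis=1).mean())


def consistency_loss(
    teacher_probs: np.ndarray, student_probs: np.ndarray, kind: str = "mse"
) -> float:
    """Discrepancy between teacher and perturbed-student probabilities.

    ``mse`` (default): mean squared difference over nodes and classes.
    ``kl``: mean KL(teacher || student) per node.
    """
    t = np.asarray(teacher_probs, dtype=np.float64)
    s = np.asarray(student_probs, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError("probability matrices must share a shape")
    if kind == "mse":
        return float(((t - s) ** 2).mean())
    if kind == "kl":
        ratio = np.log(np.maximum(t, _EPS)) - np.log(np.maximum(s, _EPS))
        return float((t * ratio).sum(axis=1).mean())
    raise ValueError(f"unknown consistency kind {kind!r}")


def total_loss(
    state: TeacherStudentState,
    A_hat: NormalizedAdjacency | np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
    consistency: str = "mse",
) -> float:
    """Supervised CE on labeled nodes + lambda * consistency on all nodes.

    The perturbed student output is shared between both terms, as in
    training. ``y`` holds class codes with UNLABELED (-1) for hidden nodes.
    """
    y = np.asarray(y)
    labeled = y != UNLABELED
    if rng is None:
        rng = np.random.default_rng(0)
    student_probs = gcn_forward(A_hat, X, state.student, perturb=True,
                                dropout=state.dropout, rng=rng)
    C = student_probs.shape[1]
    onehot = np.eye(C)[y[labeled]]
    ce = supervised_ce_loss(student_probs[labeled], onehot)
    if state.lambda_weight == 0.0:
        return ce
    teacher_probs = gcn_forward(A_hat, X, state.teacher, perturb=False)
    return ce + state.lambda_weight * consistency_loss(
        teacher_probs, student_probs, consistency
    )


# ----------------------------------------------------------------------- EMA
def ema_update(state: TeacherStudentState) -> TeacherStudentState:
    """Teacher <- alpha * teacher + (1 - alpha) * student; step increments."""
    a = state.alpha_ema
    for t_p, s_p in zip(state.teacher.tensors(), state.student.tensors()):
        t_p.value = a * t_p.value + (1.0 - a) * s_p.value
    state.step += 1
    return state


def consistency_ramp(epoch: int, epochs: int, ramp_fraction: float, lambda_max: float) -> float:
    """Sigmoid-shaped ramp of the consistency weight over early training."""
    ramp_epochs = max(1, int(round(ramp_fraction * epochs)))
    if epoch >= ramp_epochs:
        return lambda_max
    frac = epoch / ramp_epochs
    return lambda_max * float(np.exp(-5.0 * (1.0 - frac) ** 2))


# ------------------------------------------------------------------ training
def _init_params(
    input_dim: int, hidden_dim: int, n_classes: int, rng: np.random.Generator
) -> GCNParams:
    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)), requires_grad=True)

    return GCNParams(theta1=glorot(input_dim, hidden_dim), theta2=glorot(hidden_dim, n_classes))


def fit(
    X: np.ndarray,
    A_hat: NormalizedAdjacency,
    y: np.ndarray,
    n_classes: int,
    config: SEGCNConfig,
    checkpoint_every: int | None = None,
    on_checkpoint=None,
) -> tuple[TeacherStudentState, pd.DataFrame]:
    """Train the mean-teacher GCN transductively.

    ``y`` holds class codes for training-labeled nodes and UNLABELED (-1)
    everywhere else (validation/test nodes included: they participate only
    through the graph and the consistency term). Deterministic given
    ``config.seed`` — initialisation and the dropout mask stream are both
    derived from it.

    If ``checkpoint_every`` is set, ``on_checkpoint(epoch, state)`` fires
    after every that-many epochs and once more after the final epoch (used
    by the biomarker extraction schedule).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    labeled_idx = np.flatnonzero(y != UNLABELED)
    if labeled_idx.size == 0:
        raise ValueError("no labeled nodes to train on")
    present = np.unique(y[labeled_idx])
    if present.size < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"classes {missing} have no labeled node in the training mask")

    ss = np.random.SeedSequence(config.seed)
    init_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    student = _init_params(X.shape[1], config.hidden_dim, n_classes, init_rng)
    teacher = student.detached_copy()
    state = TeacherStudentState(
        student=student,
        teacher=teacher,
        alpha_ema=config.alpha_ema,
        lambda_weight=0.0,
        dropout=config.dropout,
    )
    opt = Adam(student.tensors(), lr=config.learning_rate)
    onehot = np.eye(n_classes)[y[labeled_idx]]
    onehot_t = Tensor(onehot)
    X_t = Tensor(X)
    A = A_hat.matrix

    records = []
    for epoch in range(config.epochs):
        lam = consistency_ramp(epoch, config.epochs, config.ramp_fraction, config.lambda_max)
        state.lambda_weight = lam

        opt.zero_grad()
        probs = _forward_t(A, X_t, student, True, config.dropout, drop_rng)
        probs_l = probs.rows(labeled_idx)
        ce = -(onehot_t * probs_l.log_clamped()).sum() * (1.0 / labeled_idx.size)

        teacher_probs = gcn_forward(A, X, teacher, perturb=False)
        if config.consistency == "mse":
            cons = (probs - Tensor(teacher_probs)).square().mean()
        else:  # KL(teacher || student): only -t * log s carries gradient
            cons = -(Tensor(teacher_probs) * probs.log_clamped()).sum() * (
                1.0 / probs.value.shape[0]
            )
        loss = ce + cons * lam

        value = float(loss.value)
        if not np.isfinite(value):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        ema_update(state)

        if (
            checkpoint_every is not None
            and on_checkpoint is not None
            and ((epoch + 1) % checkpoint_every == 0 or epoch + 1 == config.epochs)
        ):
            on_checkpoint(epoch + 1, state)

        pred_l = probs.value[labeled_idx].argmax(axis=1)
        records.append(
            {
                "epoch": epoch,
                "ce_loss": float(ce.value),
                "cons_loss": float(cons.value),
                "lambda": lam,
                "total": value,
                "labeled_acc": float((pred_l == y[labeled_idx]).mean()),
            }
        )
    return state, pd.DataFrame.from_records(records)


def predict(
    state: TeacherStudentState,
    A_hat: NormalizedAdjacency,
    X: np.ndarray,
    model: str = "teacher",
) -> tuple[np.ndarray, np.ndarray]:
    """Unperturbed forward pass; argmax with ties to the lowest class index.

    The teacher is the evaluation model; ``model="student"`` is available
    for ablation.
    """
    params = state.teacher if model == "teacher" else state.student
    probs = gcn_forward(A_hat, X, params, perturb=False)
    return probs.argmax(axis=1), probs
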