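"""Attention autoencoder: latent feature learning over concatenated omics.

The concatenated omics matrix X (N samples x P features) is compressed by a
dense encoder to a K-dimensional latent representation H, refined by a
multi-head scaled dot-product self-attention block (residual connection +
layer normalisation, then a position-wise feedforward block with its own
residual + normalisation), and reconstructed by a mirror decoder. Training
minimises the mean squared reconstruction error; downstream stages use only
the encoder half.

Attention runs across the N samples by default (the latent matrix H
left-multiplies the projection matrices, so rows — samples — are the
attention positions and the attention matrix is N x N). A ``features`` axis
mode is available in which each sample's latent vector is split into
equal-width tokens and attention runs across those tokens per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor

__all__ = [
    "EncoderConfig",
    "AttentionWeights",
    "LatentRepresentation",
    "encode",
    "decode",
    "reconstruction_loss",
    "scaled_dot_attention_head",
    "attention_matrix",
    "multi_head_self_attention",
    "train_encoder",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and training knobs for the attention autoencoder."""

    input_dim: int
    latent_dim: int = 200
    n_head: int = 4
    ff_width: int | None = None  # default 2 * latent_dim
    activation: str = "relu"  # "relu" | "linear" (encoder dense layer)
    use_attention: bool = True
    attention_axis: str = "samples"  # "samples" | "features"
    n_feature_tokens: int = 3  # tokens per sample in "features" mode
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_head < 1:
            raise ValueError("n_head must be >= 1")
        if self.attention_axis not in {"samples", "features"}:
            raise ValueError(f"unknown attention_axis {self.attention_axis!r}")
        d_model = self.d_model
        if d_model % self.n_head != 0:
            raise ValueError(
                f"attention width {d_model} not divisible by n_head={self.n_head}"
            )
        if self.activation not in {"relu", "linear"}:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def d_model(self) -> int:
        """Width of the attention positions' vectors."""
        if self.attention_axis == "features":
            if self.latent_dim % self.n_feature_tokens != 0:
                raise ValueError("latent_dim must be divisible by n_feature_tokens")
            return self.latent_dim // self.n_feature_tokens
        return self.latent_dim

    @property
    def d_head(self) -> int:
        """Per-head projection width (d_Q = d_K = d_V = d_model / h)."""
        return self.d_model // self.n_head

    @property
    def ff_width_resolved(self) -> int:
        return self.ff_width if self.ff_width is not None else 2 * self.latent_dim


@dataclass
class AttentionWeights:
    """All trainable parameters of the autoencoder, as autodiff tensors."""

    W_enc: Tensor
    b_enc: Tensor
    W_q: list[Tensor]
    W_k: list[Tensor]
    W_v: list[Tensor]
    W_o: Tensor
    b_o: Tensor
    ln1_gain: Tensor
    ln1_bias: Tensor
    W_ff1: Tensor
    b_ff1: Tensor
    W_ff2: Tensor
    b_ff2: Tensor
    ln2_gain: Tensor
    ln2_bias: Tensor
    W_dec: Tensor
    b_dec: Tensor

    def all_params(self) -> list[Tensor]:
        out = [self.W_enc, self.b_enc]
        out += self.W_q + self.W_k + self.W_v
        out += [self.W_o, self.b_o, self.ln1_gain, self.ln1_bias,
                self.W_ff1, self.b_ff1, self.W_ff2, self.b_ff2,
                self.ln2_gain, self.ln2_bias, self.W_dec, self.b_dec]
        return out

    def save(self, path) -> None:
        """Write all parameter matrices to one .npz archive."""
        arrays = {"W_enc": self.W_enc.value, "b_enc": self.b_enc.value,
                  "W_o": self.W_o.value, "b_o": self.b_o.value,
                  "ln1_gain": self.ln1_gain.value, "ln1_bias": self.ln1_bias.value,
                  "W_ff1": self.W_ff1.value, "b_ff1": self.b_ff1.value,
                  "W_ff2": self.W_ff2.value, "b_ff2": self.b_ff2.value,
                  "ln2_gain": self.ln2_gain.value, "ln2_bias": self.ln2_bias.value,
                  "W_dec": self.W_dec.value, "b_dec": self.b_dec.value}
        for i, (q, k, v) in enumerate(zip(self.W_q, self.W_k, self.W_v)):
            arrays[f"W_q{i}"] = q.value
            arrays[f"W_k{i}"] = k.value
            arrays[f"W_v{i}"] = v.value
        np.savez(path, **arrays)


@dataclass(frozen=True)
class LatentRepresentation:
    """Encoder output H aligned to the dataset's sample order."""

    H: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        H = np.asarray(self.H, dtype=np.float64)
        object.__setattr__(self, "H", H)
        if H.shape[0] != len(self.sample_ids):
            raise ValueError("H row count must match sample_ids")
        if not np.isfinite(H).all():
            raise ValueError("latent representation contains non-finite entries")


def init_weights(config: EncoderConfig, rng: np.random.Generator) -> AttentionWeights:
    """Glorot-uniform initialisation of every parameter matrix."""
    P, K = config.input_dim, config.latent_dim
    d_model, d = config.d_model, config.d_head
    F = config.ff_width_resolved

    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    return AttentionWeights(
        W_enc=glorot(P, K), b_enc=zeros(1, K),
        W_q=[glorot(d_model, d) for _ in range(config.n_head)],
        W_k=[glorot(d_model, d) for _ in range(config.n_head)],
        W_v=[glorot(d_model, d) for _ in range(config.n_head)],
        W_o=glorot(d_model, d_model), b_o=zeros(1, d_model),
        ln1_gain=ones(1, d_model), ln1_bias=zeros(1, d_model),
        W_ff1=glorot(d_model, F), b_ff1=zeros(1, F),
        W_ff2=glorot(F, d_model), b_ff2=zeros(1, d_model),
        ln2_gain=ones(1, d_model), ln2_bias=zeros(1, d_model),
        W_dec=glorot(K, P), b_dec=zeros(1, P),
    )


# ------------------------------------------------------------ forward pieces
def _attention_head_t(H: Tensor, W_q: Tensor, W_k: Tensor, W_v: Tensor) -> Tensor:
    """One scaled dot-product head on the tape: softmax(QK^T/sqrt(d_K)) V."""
    Q = H @ W_q
    K = H @ W_k
    V = H @ W_v
    d_k = W_k.value.shape[1]
    logits = (Q @ K.T) * (1.0 / np.sqrt(d_k))
    return logits.softmax_rows() @ V


def _attention_block_t(H: Tensor, w: AttentionWeights) -> Tensor:
    """Multi-head attention + residual + layer norm, then feedforward block."""
    heads = [_attention_head_t(H, q, k, v) for q, k, v in zip(w.W_q, w.W_k, w.W_v)]
    multi = heads[0].concat_cols(heads[1:]) @ w.W_o + w.b_o
    H1 = (H + multi).layer_norm_rows() * w.ln1_gain + w.ln1_bias
    ff = (H1 @ w.W_ff1 + w.b_ff1).relu() @ w.W_ff2 + w.b_ff2
    return (H1 + ff).layer_norm_rows() * w.ln2_gain + w.ln2_bias


def _encode_t(X: Tensor, w: AttentionWeights, config: EncoderConfig) -> Tensor:
    H0 = X @ w.W_enc + w.b_enc
    if config.activation == "relu":
        H0 = H0.relu()
    if not config.use_attention:
        return H0
    if config.attention_axis == "samples":
        return _attention_block_t(H0, w)
    # features mode: split each sample's latent vector into equal tokens and
    # attend across tokens, sharing weights across samples
    m = config.n_feature_tokens
    d = config.d_model
    rows = []
    for i in range(X.value.shape[0]):
        tokens = H0.rows(np.array([i])).reshape(m, d)
        out = _attention_block_t(tokens, w)
        rows.append(out.reshape(1, m * d))
    return rows[0].concat_rows(rows[1:])


def _decode_t(H: Tensor, w: AttentionWeights) -> Tensor:
    return H @ w.W_dec + w.b_dec


# --------------------------------------------------------------- public ops
def encode(
    X: np.ndarray,
    weights: AttentionWeights,
    config: EncoderConfig,
    sample_ids: tuple[str, ...] | None = None,
) -> LatentRepresentation:
    """Deterministic evaluation-mode encoding of X to the latent space."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != config.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, config expects {config.input_dim}")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    H = _encode_t(Tensor(X), weights, config).value
    if sample_ids is None:
        sample_ids = tuple(f"s{i}" for i in range(X.shape[0]))
    return LatentRepresentation(H=H, sample_ids=tuple(sample_ids))


def decode(H: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    return _decode_t(Tensor(np.asarray(H, dtype=np.float64)), weights).value


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray, reduction: str = "mean") -> float:
    """Squared Frobenius norm of X - X_hat, mean- or sum-reduced."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    sq = float(((X - X_hat) ** 2).sum())
    if reduction == "sum":
        return sq
    if reduction == "mean":
        return sq / X.size
    raise ValueError(f"unknown reduction {reduction!r}")


def scaled_dot_attention_head(
    H: np.ndarray, W_q: np.ndarray, W_k: np.ndarray, W_v: np.ndarray
) -> np.ndarray:
    """softmax(H W_q (H W_k)^T / sqrt(d_K)) (H W_v) — one head, eval mode."""
    out = _attention_head_t(
        Tensor(np.asarray(H, dtype=np.float64)),
        Tensor(np.asarray(W_q, dtype=np.float64)),
        Tensor(np.asarray(W_k, dtype=np.float64)),
        Tensor(np.asarray(W_v, dtype=np.float64)),
    ).value
    if not np.isfinite(out).all():
        raise ValueError("non-finite intermediate in attention head")
    return out


def attention_matrix(H: np.ndarray, W_q: np.ndarray, W_k: np.ndarray) -> np.ndarray:
    """The row-stochastic N x N attention matrix of one head (for inspection)."""
    H = np.asarray(H, dtype=np.float64)
    Q = H @ np.asarray(W_q, dtype=np.float64)
    K = H @ np.asarray(W_k, dtype=np.float64)
    logits = Q @ K.T / np.sqrt(np.asarray(W_k).shape[1])
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def multi_head_self_attention(H: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Full attention block (multi-head + W_o + residual + layer norm + FF)."""
    return _attention_block_t(Tensor(np.asarray(H, dtype=np.float64)), weights).value


# ----------------------------------------------------------------- training
def train_encoder(
    X: np.ndarray,
    config: EncoderConfig,
    sample_ids: tuple[str, ...] | None = None,
) -> tuple[AttentionWeights, LatentRepresentation, list[float]]:
    """Fit the autoencoder by Adam on the mean squared reconstruction error.

    Returns the trained weights, the evaluation-mode latent representation
    of ``X``, and the per-epoch loss trace. Training runs on all samples
    (labeled and unlabeled alike): autoencoding is unsupervised.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != config.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, config expects {config.input_dim}")
    rng = np.random.default_rng(config.seed)
    weights = init_weights(config, rng)
    opt = Adam(weights.all_params(), lr=config.learning_rate)
    X_t = Tensor(X)
    trace: list[float] = []
    for epoch in range(config.epochs):
        opt.zero_grad()
        H = _encode_t(X_t, weights, config)
        X_hat = _decode_t(H, weights)
        loss = (X_t - X_hat).square().mean()
        value = float(loss.value)
        if not np.isfinite(value):
            raise FloatingPointError(f"reconstruction loss diverged at epoch {epoch}")
        trace.append(value)
        loss.backward()
        opt.step()
    latent = encode(X, weights, config, sample_ids)
    return weights, latent, trace
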