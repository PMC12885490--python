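"""Conv-transformer decoder for four-class MI-speed classification.

Architecture (conv module → self-attention module → classification module):

1. **Convolution module** — a bank of temporal kernels ``K`` (one FIR filter
   per feature) applied along time, a spatial filter matrix ``W`` projecting
   each filtered multichannel signal onto one source per feature, an ELU
   nonlinearity, and average pooling that turns the sequence into tokens.
2. **Self-attention module** — a pre-LayerNorm transformer encoder over the
   token sequence (multi-head self-attention + GELU MLP, residual
   connections).
3. **Classification module** — LayerNorm, flatten, dropout, and a linear
   head producing one score per class.

Implemented directly in numpy with hand-derived gradients (see ``nn``);
training uses Adam on the cross-entropy with early stopping on validation
loss.  Every stochastic element (init, batch order, dropout) is driven by
the single training seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import EpochSet


@dataclass(frozen=True)
class ConformerConfig:
    n_temporal_filters: int = 40
    temporal_kernel_len: int = 25  # samples
    pool_len: int = 75
    pool_stride: int = 15
    embed_dim: int = 40
    n_attention_layers: int = 2
    n_heads: int = 4
    dropout: float = 0.5
    n_classes: int = 4
    mlp_ratio: float = 2.0
    # training
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 20

    def validate(self, n_samples: int | None = None) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if n_samples is not None:
            if self.temporal_kernel_len >= n_samples or self.pool_len >= n_samples:
                raise ValueError("kernel/pool lengths must be smaller than the epoch")


@dataclass
class TrainingLogEntry:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


class Conformer:
    """The decoder with explicit parameters and a full backward pass."""

    def __init__(self, config: ConformerConfig, n_channels: int, n_samples: int, seed: int = 0):
        config.validate(n_samples)
        self.config = config
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.seed = seed
        c = config
        t_conv = n_samples - c.temporal_kernel_len + 1
        self.n_tokens = (t_conv - c.pool_len) // c.pool_stride + 1
        if self.n_tokens < 1:
            raise ValueError("epoch too short for the configured pooling")
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        E, F = c.embed_dim, c.n_temporal_filters

        def glorot(*shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape)

        p = {
            "K": glorot(F, c.temporal_kernel_len),
            "W": glorot(F, n_channels),
        }
        if E != F:
            p["proj_w"], p["proj_b"] = glorot(F, E), np.zeros(E)
        for i in range(c.n_attention_layers):
            p[f"ln1_g{i}"], p[f"ln1_b{i}"] = np.ones(E), np.zeros(E)
            for nm in ("wq", "wk", "wv", "wo"):
                p[f"{nm}{i}"] = glorot(E, E)
            for nm in ("bq", "bk", "bv", "bo"):
                p[f"{nm}{i}"] = np.zeros(E)
            hidden = int(c.mlp_ratio * E)
            p[f"ln2_g{i}"], p[f"ln2_b{i}"] = np.ones(E), np.zeros(E)
            p[f"mlp_w1_{i}"], p[f"mlp_b1_{i}"] = glorot(E, hidden), np.zeros(hidden)
            p[f"mlp_w2_{i}"], p[f"mlp_b2_{i}"] = glorot(hidden, E), np.zeros(E)
        p["lnf_g"], p["lnf_b"] = np.ones(E), np.zeros(E)
        p["head_w"] = glorot(self.n_tokens * E, c.n_classes)
        p["head_b"] = np.zeros(c.n_classes)
        self.params = p

    # -- forward / backward ------------------------------------------------

    def forward(self, X, train: bool = False, rng=None, want_cache: bool = False):
        """Class scores for a batch. X: (B, C, T) -> (B, n_classes)."""
        if X.ndim != 3 or X.shape[1] != self.n_channels or X.shape[2] != self.n_samples:
            raise ValueError(
                f"expected batch of shape (*, {self.n_channels}, {self.n_samples}), "
                f"got {X.shape}"
            )
        c, p = self.config, self.params
        if train and rng is None:
            rng = np.random.default_rng(0)
        cache = {}
        S, cache["conv"] = nn.conv_module_forward(X, p["K"], p["W"])
        A, cache["elu"] = nn.elu_forward(S)
        P, cache["pool"] = nn.avgpool_forward(A, c.pool_len, c.pool_stride)
        tokens = np.ascontiguousarray(P.transpose(0, 2, 1))  # (B, n_tokens, F)
        cache["tokens"] = tokens
        U = tokens
        if "proj_w" in p:
            U, cache["proj"] = nn.linear_forward(U, p["proj_w"], p["proj_b"])
        U, cache["drop0"] = nn.dropout_forward(U, c.dropout, rng, train)
        for i in range(c.n_attention_layers):
            N1, cache[f"ln1_{i}"] = nn.layernorm_forward(U, p[f"ln1_g{i}"], p[f"ln1_b{i}"])
            attn_p = {nm: p[f"{nm}{i}"] for nm in ("wq", "bq", "wk", "bk", "wv", "bv", "wo", "bo")}
            O, cache[f"attn_{i}"] = nn.attention_forward(N1, attn_p, c.n_heads)
            U = U + O
            N2, cache[f"ln2_{i}"] = nn.layernorm_forward(U, p[f"ln2_g{i}"], p[f"ln2_b{i}"])
            H1, cache[f"mlp1_{i}"] = nn.linear_forward(N2, p[f"mlp_w1_{i}"], p[f"mlp_b1_{i}"])
            G, cache[f"gelu_{i}"] = nn.gelu_forward(H1)
            M, cache[f"mlp2_{i}"] = nn.linear_forward(G, p[f"mlp_w2_{i}"], p[f"mlp_b2_{i}"])
            U = U + M
        Nf, cache["lnf"] = nn.layernorm_forward(U, p["lnf_g"], p["lnf_b"])
        flat = Nf.reshape(Nf.shape[0], -1)
        flat, cache["drop1"] = nn.dropout_forward(flat, c.dropout, rng, train)
        logits, cache["head"] = nn.linear_forward(flat, p["head_w"], p["head_b"])
        if want_cache:
            return logits, cache
        return logits

    def backward(self, dlogits, cache):
        """Gradients of the loss w.r.t. all parameters and the conv-module
        output tokens.  Returns ``(grads, d_tokens)``."""
        c, p = self.config, self.params
        g = {}
        dflat, g["head_w"], g["head_b"] = nn.linear_backward(dlogits, cache["head"])
        dflat = nn.dropout_backward(dflat, cache["drop1"])
        B = dlogits.shape[0]
        dNf = dflat.reshape(B, self.n_tokens, -1)
        dU, g["lnf_g"], g["lnf_b"] = nn.layernorm_backward(dNf, cache["lnf"])
        for i in reversed(range(c.n_attention_layers)):
            dM = dU
            dG, g[f"mlp_w2_{i}"], g[f"mlp_b2_{i}"] = nn.linear_backward(dM, cache[f"mlp2_{i}"])
            dH1 = nn.gelu_backward(dG, cache[f"gelu_{i}"])
            dN2, g[f"mlp_w1_{i}"], g[f"mlp_b1_{i}"] = nn.linear_backward(dH1, cache[f"mlp1_{i}"])
            dU2, g[f"ln2_g{i}"], g[f"ln2_b{i}"] = nn.layernorm_backward(dN2, cache[f"ln2_{i}"])
            dU = dU + dU2
            dO = dU
            dN1, attn_grads = nn.attention_backward(dO, cache[f"attn_{i}"])
            for nm, val in attn_grads.items():
                g[f"{nm}{i}"] = val
            dU1, g[f"ln1_g{i}"], g[f"ln1_b{i}"] = nn.layernorm_backward(dN1, cache[f"ln1_{i}"])
            dU = dU + dU1
        dU = nn.dropout_backward(dU, cache["drop0"])
        if "proj" in cache:
            dU, g["proj_w"], g["proj_b"] = nn.linear_backward(dU, cache["proj"])
        d_tokens = dU
        dP = d_tokens.transpose(0, 2, 1)  # (B, F, n_tokens)
        dA = nn.avgpool_backward(dP, cache["pool"])
        dS = nn.elu_backward(dA, cache["elu"])
        g["K"], g["W"] = nn.conv_module_backward(dS, cache["conv"])
        return g, d_tokens

    def token_centers(self) -> np.ndarray:
        """Receptive-field center of each token, in input samples."""
        c = self.config
        starts = np.arange(self.n_tokens) * c.pool_stride
        return starts + (c.pool_len - 1) / 2.0 + (c.temporal_kernel_len - 1) / 2.0


@dataclass
class TrainedModel:
    model: Conformer
    config: ConformerConfig
    training_log: list
    seed: int
    channel_names: tuple
    fs: float
    t_min: float
    class_labels: tuple = ("rest", "slow", "medium", "fast")

    @property
    def kernels(self) -> np.ndarray:
        return self.model.params["K"]

    @property
    def spatial_filters(self) -> np.ndarray:
        return self.model.params["W"]

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "channel_names": list(self.channel_names),
            "class_labels": list(self.class_labels),
            "fs": self.fs,
            "t_min": self.t_min,
            "n_channels": self.model.n_channels,
            "n_samples": self.model.n_samples,
            "training_log": [asdict(e) for e in self.training_log],
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(d / "weights.npz", **self.model.params)

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        config = ConformerConfig(**meta["config"])
        model = Conformer(config, meta["n_channels"], meta["n_samples"], seed=meta["seed"])
        with np.load(d / "weights.npz") as z:
            model.params = {k: z[k].copy() for k in z.files}
        return cls(
            model=model,
            config=config,
            training_log=[TrainingLogEntry(**e) for e in meta["training_log"]],
            seed=meta["seed"],
            channel_names=tuple(meta["channel_names"]),
            fs=meta["fs"],
            t_min=meta["t_min"],
            class_labels=tuple(meta["class_labels"]),
        )


def forward(trained: TrainedModel, epochs: EpochSet) -> np.ndarray:
    """Deterministic (eval-mode) class scores, one row per trial."""
    return trained.model.forward(epochs.data)


def predict(trained: TrainedModel, epochs: EpochSet) -> np.ndarray:
    """Argmax class indices; ties break toward the lower class index."""
    return np.argmax(forward(trained, epochs), axis=1)


def _accuracy(scores, labels):
    return float((np.argmax(scores, axis=1) == labels).mean())


def train(
    config: ConformerConfig,
    train_epochs: EpochSet,
    val_epochs: EpochSet,
    seed: int = 0,
) -> TrainedModel:
    """Adam + cross-entropy with early stopping on validation loss."""
    counts = np.bincount(train_epochs.labels, minlength=config.n_classes)
    if (counts == 0).any():
        missing = [train_epochs.class_labels[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"training set lacks trials for classes {missing}")
    n_tr, n_ch, n_samp = train_epochs.data.shape
    ss = np.random.SeedSequence(seed)
    init_ss, order_ss, drop_ss = ss.spawn(3)
    model = Conformer(config, n_ch, n_samp, seed=init_ss.generate_state(1)[0] % (2**31))
    order_rng = np.random.default_rng(order_ss)
    drop_rng = np.random.default_rng(drop_ss)
    opt = nn.Adam(model.params, lr=config.lr)

    log: list[TrainingLogEntry] = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stall = 0
    for ep in range(config.max_epochs):
        perm = order_rng.permutation(n_tr)
        tr_loss = 0.0
        tr_correct = 0
        for start in range(0, n_tr, config.batch_size):
            idx = perm[start : start + config.batch_size]
            Xb, yb = train_epochs.data[idx], train_epochs.labels[idx]
            logits, cache = model.forward(Xb, train=True, rng=drop_rng, want_cache=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {ep} (non-finite loss {loss})"
                )
            grads, _ = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            tr_loss += loss * len(idx)
            tr_correct += int((np.argmax(logits, axis=1) == yb).sum())
        val_logits = model.forward(val_epochs.data)
        val_loss, _ = nn.cross_entropy(val_logits, val_epochs.labels)
        entry = TrainingLogEntry(
            epoch=ep,
            train_loss=tr_loss / n_tr,
            train_acc=tr_correct / n_tr,
            val_loss=float(val_loss),
            val_acc=_accuracy(val_logits, val_epochs.labels),
        )
        log.append(entry)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.params = best_params
    return TrainedModel(
        model=model,
        config=config,
        training_log=log,
        seed=seed,
        channel_names=train_epochs.channel_names,
        fs=train_epochs.fs,
        t_min=float(train_epochs.time_axis[0]),
        class_labels=train_epochs.class_labels,
    )
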