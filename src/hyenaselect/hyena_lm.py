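"""Decoder-only DNA language model built from Hyena operators.

The model is a stack of blocks, each combining an implicit long convolution
with element-wise multiplicative gating.  Three dense projections of the
input (x1, x2, v), each followed by a causal depthwise short convolution,
feed the operator

    y = x2 * causal_conv(x1 * v, h)

where the long filter ``h`` is generated per channel by a small MLP from
positional features and optionally modulated by a learnable exponential
decay.  The causal convolution is multiplication by the lower-triangular
Toeplitz matrix of ``h``, evaluated in O(L log L) with zero-padded FFTs.
Because the filter is implicit, the parameter count does not grow with the
context length.

Training minimises next-nucleotide cross-entropy; positions whose target is
a special token (PAD/UNK/SEP) are excluded from the loss.  Embeddings are
the mean of final-layer hidden states over unpadded positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .genome_io import VOCAB
from .windowing import Window

__all__ = [
    "HyenaConfig",
    "HyenaModel",
    "positional_features",
    "implicit_filter",
    "fft_causal_conv",
    "hyena_operator",
    "forward_lm",
    "train_lm",
    "evaluate_xent",
    "embed_window",
    "embed_windows",
    "init_block_params",
]

N_BASES = 4  # loss is defined over A/T/C/G targets only


@dataclass
class HyenaConfig:
    """Architecture and training hyperparameters.

    Training defaults (batch_size 16, learning_rate 6e-4, max_epochs 6,
    n_layer 2) are the published fine-tuning settings; ``l_in`` may be any
    window length up to 32,768 and defaults to a CPU-friendly 512.
    """

    l_in: int = 512
    d_model: int = 256
    n_layer: int = 2
    vocab_size: int = 7
    order: int = 2  # number of gate projections (x1, x2) besides v
    short_conv_width: int = 3
    filter_mlp_hidden: int = 32
    pos_feat_dim: int = 9
    use_decay: bool = True
    ffn_mult: int = 2
    learning_rate: float = 6e-4
    batch_size: int = 16
    max_epochs: int = 6
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l_in < 2:
            raise ValueError("l_in must be >= 2")
        if self.d_model < 1 or self.n_layer < 1:
            raise ValueError("d_model and n_layer must be >= 1")


# ---------------------------------------------------------------------------
# positional features and implicit filters


def positional_features(L: int, pos_feat_dim: int, scale: int | None = None) -> np.ndarray:
    """Deterministic per-position features feeding the filter MLP.

    Row ``t`` is the normalised index ``t/scale`` concatenated with
    sin/cos pairs at geometrically spaced frequencies.  ``scale`` defaults
    to ``L``; the model passes its fixed context length so that row ``t``
    depends on the absolute index only and filters extend consistently
    across lengths.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if scale is None:
        scale = L
    t = np.arange(L, dtype=np.float64)
    feats = [t / scale]
    n_pairs = (pos_feat_dim - 1) // 2
    if n_pairs > 0:
        f_min, f_max = 1.0 / scale, 0.5
        if n_pairs == 1:
            freqs = np.array([f_min])
        else:
            freqs = f_min * (f_max / f_min) ** (np.arange(n_pairs) / (n_pairs - 1))
        for f in freqs:
            feats.append(np.sin(2 * np.pi * f * t))
            feats.append(np.cos(2 * np.pi * f * t))
    while len(feats) < pos_feat_dim:  # odd leftover slot
        feats.append(t / scale)
    return np.stack(feats[:pos_feat_dim], axis=1)


def _implicit_filter_t(params: dict, L: int, config: HyenaConfig) -> Tensor:
    """Tape version: h[t] = MLP(pos_features(t)), optionally decay-modulated."""
    z = Tensor(positional_features(L, config.pos_feat_dim, scale=config.l_in))
    hidden = ad.sin(ad.add(ad.matmul(z, params["fm_w1"]), params["fm_b1"]))
    h = ad.add(ad.matmul(hidden, params["fm_w2"]), params["fm_b2"])
    if config.use_decay:
        alpha = ad.softplus(params["decay_raw"])  # [D], alpha >= 0
        t_norm = Tensor(np.arange(L, dtype=np.float64)[:, None] / config.l_in)
        h = ad.mul(h, ad.exp(ad.scale(ad.mul(t_norm, alpha), -1.0)))
    return h


def implicit_filter(params: dict, L: int, config: HyenaConfig) -> np.ndarray:
    """The materialised long-convolution filter h [L, d_model]."""
    return _implicit_filter_t(_ensure_tensors(params), L, config).data


# ---------------------------------------------------------------------------
# operator


def fft_causal_conv(u: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Causal per-channel convolution y[t] = sum_{s<=t} h[t-s] u[s].

    ``u`` may be [L, D] or [B, L, D]; ``h`` is [L, D].  Equivalent to
    multiplying each channel by the lower-triangular Toeplitz matrix of its
    filter; computed with zero-padded FFTs of length >= 2L-1.
    """
    u = np.asarray(u, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if u.shape[-2:] != h.shape[-2:]:
        raise ValueError(f"shape mismatch: u {u.shape} vs h {h.shape}")
    return ad._cconv(u, h, u.shape[-2])


def _operator_t(u: Tensor, params: dict, config: HyenaConfig) -> Tensor:
    """Hyena operator on a [B, L, D] tape tensor."""
    L = u.data.shape[-2]

    def proj(w, b, k):
        return ad.depthwise_causal_conv(
            ad.add(ad.matmul(u, params[w]), params[b]), params[k]
        )

    x1 = proj("wx1", "bx1", "kx1")
    x2 = proj("wx2", "bx2", "kx2")
    v = proj("wv", "bv", "kv")
    h = _implicit_filter_t(params, L, config)
    return ad.mul(x2, ad.causal_fft_conv(ad.mul(x1, v), h))


def hyena_operator(u: np.ndarray, params: dict, config: HyenaConfig) -> np.ndarray:
    """Apply one Hyena operator to ``u`` ([L, D] or [B, L, D])."""
    u = np.asarray(u, dtype=np.float64)
    squeeze = u.ndim == 2
    if squeeze:
        u = u[None]
    out = _operator_t(Tensor(u), _ensure_tensors(params), config).data
    return out[0] if squeeze else out


def _ensure_tensors(params: dict) -> dict:
    return {
        k: (v if isinstance(v, Tensor) else Tensor(v)) for k, v in params.items()
    }


# ---------------------------------------------------------------------------
# model


def init_block_params(config: HyenaConfig, rng: np.random.Generator) -> dict:
    """Initialise one block's parameters.

    Dense weights use 1/sqrt(fan_in) Gaussian init; short-conv kernels start
    near the identity (lag-0 tap 1) so information flows from step one; the
    filter MLP's output layer starts small so the long-convolution branch
    grows in gradually under the residual connections.
    """
    d, hdim, p, w = (
        config.d_model,
        config.filter_mlp_hidden,
        config.pos_feat_dim,
        config.short_conv_width,
    )

    def dense(fan_in, fan_out, s=1.0):
        return Tensor(rng.normal(0, s / np.sqrt(fan_in), (fan_in, fan_out)),
                      requires_grad=True)

    def kernel():
        k = rng.normal(0, 0.02, (w, d))
        k[0] += 1.0
        return Tensor(k, requires_grad=True)

    params = {
        "ln1_g": Tensor(np.ones(d), requires_grad=True),
        "ln1_b": Tensor(np.zeros(d), requires_grad=True),
        "wx1": dense(d, d), "bx1": Tensor(np.zeros(d), requires_grad=True),
        "wx2": dense(d, d), "bx2": Tensor(np.zeros(d), requires_grad=True),
        "wv": dense(d, d), "bv": Tensor(np.zeros(d), requires_grad=True),
        "kx1": kernel(), "kx2": kernel(), "kv": kernel(),
        "fm_w1": Tensor(rng.normal(0, 1.0, (p, hdim)), requires_grad=True),
        "fm_b1": Tensor(rng.uniform(-np.pi, np.pi, hdim), requires_grad=True),
        "fm_w2": dense(hdim, d, s=0.3),
        "fm_b2": Tensor(np.zeros(d), requires_grad=True),
        "w_out": dense(d, d),
        "b_out": Tensor(np.zeros(d), requires_grad=True),
        "ln2_g": Tensor(np.ones(d), requires_grad=True),
        "ln2_b": Tensor(np.zeros(d), requires_grad=True),
        "ffn_w1": dense(d, config.ffn_mult * d),
        "ffn_b1": Tensor(np.zeros(config.ffn_mult * d), requires_grad=True),
        "ffn_w2": dense(config.ffn_mult * d, d),
        "ffn_b2": Tensor(np.zeros(d), requires_grad=True),
    }
    if config.use_decay:
        params["decay_raw"] = Tensor(np.full(d, 0.5), requires_grad=True)
    return params


class HyenaModel:
    """Trained parameters plus configuration; serialises to a single .npz."""

    def __init__(self, config: HyenaConfig, rng: np.random.Generator | None = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        d, v = config.d_model, config.vocab_size
        self.embed = Tensor(rng.normal(0, 0.02, (v, d)), requires_grad=True)
        self.blocks = [init_block_params(config, rng) for _ in range(config.n_layer)]
        self.lnf_g = Tensor(np.ones(d), requires_grad=True)
        self.lnf_b = Tensor(np.zeros(d), requires_grad=True)
        self.lm_head = Tensor(rng.normal(0, 1 / np.sqrt(d), (d, v)), requires_grad=True)
        self.lm_bias = Tensor(np.zeros(v), requires_grad=True)
        self.training_log: list[dict] = []
        self.vocab_hash = VOCAB.content_hash()

    # -- parameter plumbing ------------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out = [("embed", self.embed), ("lnf_g", self.lnf_g), ("lnf_b", self.lnf_b),
               ("lm_head", self.lm_head), ("lm_bias", self.lm_bias)]
        for i, block in enumerate(self.blocks):
            out.extend((f"block{i}.{k}", t) for k, t in sorted(block.items()))
        return out

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    # -- forward -----------------------------------------------------------
    def forward_hidden(self, ids: np.ndarray) -> Tensor:
        """Final-layer hidden states [B, L, d_model] for token ids [B, L]."""
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None]
        if ids.shape[1] > self.config.l_in:
            raise ValueError(
                f"window length {ids.shape[1]} exceeds model L_in {self.config.l_in}"
            )
        u = ad.embedding(self.embed, ids)
        for p in self.blocks:
            z = ad.layer_norm(u, p["ln1_g"], p["ln1_b"])
            z = _operator_t(z, p, self.config)
            z = ad.add(ad.matmul(z, p["w_out"]), p["b_out"])
            u = ad.add(u, z)
            z2 = ad.layer_norm(u, p["ln2_g"], p["ln2_b"])
            z2 = ad.gelu(ad.add(ad.matmul(z2, p["ffn_w1"]), p["ffn_b1"]))
            z2 = ad.add(ad.matmul(z2, p["ffn_w2"]), p["ffn_b2"])
            u = ad.add(u, z2)
        return ad.layer_norm(u, self.lnf_g, self.lnf_b)

    def forward_logits(self, ids: np.ndarray) -> Tensor:
        hidden = self.forward_hidden(ids)
        return ad.add(ad.matmul(hidden, self.lm_head), self.lm_bias)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: t.data for name, t in self.named_parameters()}
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __log__=json.dumps(self.training_log),
            __vocab_hash__=self.vocab_hash,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "HyenaModel":
        data = np.load(path, allow_pickle=False)
        config = HyenaConfig(**json.loads(str(data["__config__"])))
        model = cls(config)
        for name, t in model.named_parameters():
            t.data = data[name].copy()
        model.training_log = json.loads(str(data["__log__"]))
        model.vocab_hash = str(data["__vocab_hash__"])
        return model


# ---------------------------------------------------------------------------
# spec-level operations


def forward_lm(model: HyenaModel, window: Window) -> np.ndarray:
    """Vocabulary logits [L, vocab_size] for one window (eval mode)."""
    return model.forward_logits(window.token_ids[None]).data[0]


def _targets_for(ids: np.ndarray, pad_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Next-token targets and loss mask; special-token targets are excluded."""
    targets = np.zeros_like(ids)
    targets[:, :-1] = ids[:, 1:]
    mask = np.zeros(ids.shape, dtype=bool)
    mask[:, :-1] = (ids[:, 1:] < N_BASES) & pad_mask[:, :-1]
    return targets.astype(np.int64), mask


def _stack(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray]:
    ids = np.stack([w.token_ids for w in windows]).astype(np.int64)
    mask = np.stack([w.pad_mask for w in windows])
    return ids, mask


def train_lm(
    corpus: Sequence[Window],
    config: HyenaConfig,
    val_corpus: Sequence[Window] | None = None,
    model: HyenaModel | None = None,
) -> HyenaModel:
    """Train (or continue training) on next-nucleotide prediction.

    Runs ``max_epochs`` passes of minibatch Adam with global-norm gradient
    clipping; the per-epoch mean training loss (and held-out loss when a
    validation corpus is given) is appended to ``model.training_log``.
    Fully deterministic under a fixed config seed on a single device.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("training corpus is empty")
    if model is None:
        model = HyenaModel(config)
    ids, pad = _stack(corpus)
    targets, loss_mask = _targets_for(ids, pad)
    if not loss_mask.any():
        raise ValueError("corpus has no nucleotide targets to learn from")
    rng = np.random.default_rng(config.seed + 1)
    opt = ad.Adam(model.parameters(), lr=config.learning_rate)
    n = len(corpus)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = perm[lo : lo + config.batch_size]
            if not loss_mask[sel].any():
                continue
            opt.zero_grad()
            logits = model.forward_logits(ids[sel])
            loss = ad.masked_cross_entropy(logits, targets[sel], loss_mask[sel])
            loss.backward()
            ad.clip_global_norm(model.parameters(), config.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_corpus is not None:
            entry["val_loss"] = evaluate_xent(model, val_corpus)
        model.training_log.append(entry)
    return model


def evaluate_xent(model: HyenaModel, corpus: Sequence[Window],
                  batch_size: int = 32) -> float:
    """Mean next-nucleotide cross-entropy (nats/token) over a corpus."""
    ids, pad = _stack(corpus)
    targets, mask = _targets_for(ids, pad)
    total, count = 0.0, 0
    for lo in range(0, len(ids), batch_size):
        sel = slice(lo, lo + batch_size)
        if not mask[sel].any():
            continue
        logits = model.forward_logits(ids[sel])
        loss = ad.masked_cross_entropy(logits, targets[sel], mask[sel])
        n_here = int(mask[sel].sum())
        total += float(loss.data) * n_here
        count += n_here
    if count == 0:
        raise ValueError("no nucleotide targets in evaluation corpus")
    return total / count


def embed_window(model: HyenaModel, window: Window) -> np.ndarray:
    """Mean of final hidden states over unpadded positions: [d_model]."""
    return embed_windows(model, [window])[0]


def embed_windows(
    model: HyenaModel, windows: Sequence[Window], batch_size: int = 32
) -> np.ndarray:
    """Batched window embeddings [n_windows, d_model] (pad-mask pooled)."""
    out = np.empty((len(windows), model.config.d_model))
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo : lo + batch_size]
        ids, pad = _stack(chunk)
        counts = pad.sum(axis=1)
        if (counts == 0).any():
            bad = int(np.argmax(counts == 0))
            raise ValueError(
                f"window {lo + bad} ({chunk[bad].chrom_id}:{chunk[bad].start}) "
                "is all padding; nothing to pool"
            )
        hidden = model.forward_hidden(ids).data
        out[lo : lo + len(chunk)] = (
            (hidden * pad[..., None]).sum(axis=1) / counts[:, None]
        )
    return out
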