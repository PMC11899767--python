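"""Small 1-D convolutional network predictor on feature vectors.

Treats the per-sample feature vector as a length-F signal with one input
channel, applies a causal 1-D convolution bank, ReLU, global average
pooling and a dense head.  Trained with Adam on the package's autodiff
engine; deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Conv1DNet:
    """sklearn-style fit/predict wrapper (regression or classification)."""

    def __init__(
        self,
        task: str = "regression",
        seed: int = 0,
        n_channels: int = 16,
        kernel_width: int = 5,
        lr: float = 3e-3,
        epochs: int = 300,
        batch_size: int = 64,
    ):
        if task not in {"regression", "classification"}:
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.seed = seed
        self.n_channels = n_channels
        self.kernel_width = kernel_width
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self._params: dict | None = None
        self.classes_: np.ndarray | None = None
        self._x_mean = self._x_std = None

    # -- internals ---------------------------------------------------------
    def _init(self, n_feat: int, n_out: int, rng: np.random.Generator) -> dict:
        c, w = self.n_channels, self.kernel_width
        flat = n_feat * c
        return {
            "conv": Tensor(rng.normal(0, 1.0 / np.sqrt(w), (w, 1, c)), requires_grad=True),
            "conv_b": Tensor(np.zeros(c), requires_grad=True),
            "head_w": Tensor(rng.normal(0, 1.0 / np.sqrt(flat), (flat, n_out)), requires_grad=True),
            "head_b": Tensor(np.zeros(n_out), requires_grad=True),
        }

    def _forward(self, x: np.ndarray) -> Tensor:
        p = self._params
        sig = Tensor(x[..., None])  # [B, F, 1]
        z = ad.relu(ad.add(ad.conv1d_causal(sig, p["conv"]), p["conv_b"]))
        flat = ad.reshape(z, (x.shape[0], -1))  # keep position information
        return ad.add(ad.matmul(flat, p["head_w"]), p["head_b"])

    def _standardise(self, x: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            self._x_mean = x.mean(axis=0)
            self._x_std = x.std(axis=0)
            self._x_std[self._x_std == 0] = 1.0
        return (x - self._x_mean) / self._x_std

    # -- sklearn-ish API -----------------------------------------------------
    def fit(self, x, y) -> "Conv1DNet":
        x = self._standardise(np.asarray(x, dtype=np.float64), fit=True)
        rng = np.random.default_rng(self.seed)
        if self.task == "classification":
            self.classes_, y_idx = np.unique(np.asarray(y), return_inverse=True)
            n_out = len(self.classes_)
            y_arr = y_idx.astype(np.int64)
        else:
            y_arr = np.asarray(y, dtype=np.float64)
            n_out = 1
        self._params = self._init(x.shape[1], n_out, rng)
        opt = ad.Adam(self._params.values(), lr=self.lr)
        n = len(x)
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                sel = perm[lo : lo + self.batch_size]
                opt.zero_grad()
                out = self._forward(x[sel])
                if self.task == "classification":
                    loss = ad.softmax_cross_entropy(out, y_arr[sel])
                else:
                    diff = ad.sub(out, Tensor(y_arr[sel][:, None]))
                    loss = ad.scale(ad.mean_axis(ad.mean_axis(ad.mul(diff, diff), 1), 0), 1.0)
                loss.backward()
                ad.clip_global_norm(list(self._params.values()), 1.0)
                opt.step()
        return self

    def predict(self, x) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("Conv1DNet is not fitted")
        x = self._standardise(np.asarray(x, dtype=np.float64), fit=False)
        out = self._forward(x).data
        if self.task == "classification":
            return self.classes_[np.argmax(out, axis=1)]
        return out[:, 0]
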