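"""Minimal fully-connected neural network on numpy.

Feed-forward net with ReLU hidden layers, inverted dropout, L2 weight
penalty and Adam, supporting squared-error regression and class-weighted
binary cross-entropy. Dropout is active only during training; inference is
deterministic. All randomness (init, mini-batch order, dropout masks,
validation split) comes from a single seeded generator, so training is
reproducible bit-for-bit for a fixed configuration and seed.

Written for small tabular problems (tens of features, hundreds of samples)
where full- or large-batch Adam converges in seconds; this is the training
engine behind the assay quantifier and the acute classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["NetworkConfig", "MLP"]


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    Defaults: two ReLU hidden layers of 512 and 64 nodes with 50% dropout,
    Adam at 1e-3, up to 2000 epochs with early stopping on a 15% validation
    split. ``loss`` is "mse" (used on a transformed regression target) or
    "bce" (sigmoid output, class-weighted binary cross-entropy).
    """

    hidden: tuple[int, ...] = (512, 64)
    dropout: float = 0.5
    l2: float = 1e-4
    lr: float = 1e-3
    batch_size: int | None = None  # None = full batch
    loss: str = "mse"
    epochs: int = 2000
    patience: int = 50
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden layer sizes must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


class MLP:
    """Fully-connected network trained with Adam and early stopping."""

    def __init__(self, config: NetworkConfig | None = None, **overrides):
        cfg = config or NetworkConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.n_features_: int | None = None
        self.history_: list[float] = []

    # -- internals -------------------------------------------------------
    def _init_params(self, n_in: int, rng: np.random.Generator) -> None:
        sizes = [n_in, *self.config.hidden, 1]
        self.weights_ = [
            rng.normal(0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.n_features_ = n_in

    def _forward(self, X, rng=None):
        """Forward pass; dropout masks drawn only when ``rng`` is given."""
        drop = self.config.dropout
        acts, masks = [X], []
        h = X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            if i < len(self.weights_) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and drop > 0:
                    mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(h)
            else:
                h = z
        return h[:, 0], acts, masks

    def _loss_grad(self, out, y, w):
        if self.config.loss == "mse":
            resid = out - y
            loss = float(np.average(resid**2, weights=w))
            grad = 2.0 * resid * w / w.sum()
        else:
            p = 1.0 / (1.0 + np.exp(-out))
            eps = 1e-12
            loss = float(
                np.average(
                    -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)),
                    weights=w,
                )
            )
            grad = (p - y) * w / w.sum()
        return loss, grad

    # -- API -------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "MLP":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(X)
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        rng = np.random.default_rng(cfg.seed)
        self._init_params(X.shape[1], rng)

        # held-out validation split for early stopping; for classification
        # the split is stratified by class so a rare class cannot vanish
        # from the monitoring set
        n_val = int(round(cfg.val_fraction * n)) if cfg.patience else 0
        if n_val and cfg.loss == "bce":
            val_parts, tr_parts = [], []
            for cls in (0.0, 1.0):
                cls_idx = rng.permutation(np.where(y == cls)[0])
                k = max(1, int(round(cfg.val_fraction * len(cls_idx))))
                k = min(k, max(len(cls_idx) - 1, 0))
                val_parts.append(cls_idx[:k])
                tr_parts.append(cls_idx[k:])
            val_idx = np.concatenate(val_parts)
            tr_idx = np.concatenate(tr_parts)
        else:
            idx = rng.permutation(n)
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(tr_idx) == 0:
                tr_idx, val_idx = idx, idx[:0]
        Xt, yt, wt = X[tr_idx], y[tr_idx], w[tr_idx]
        Xv, yv, wv = X[val_idx], y[val_idx], w[val_idx]

        m_w = [np.zeros_like(W) for W in self.weights_]
        v_w = [np.zeros_like(W) for W in self.weights_]
        m_b = [np.zeros_like(b) for b in self.biases_]
        v_b = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best = np.inf
        best_params = None
        stall = 0
        batch = cfg.batch_size or len(Xt)
        self.history_ = []

        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(Xt))
            for start in range(0, len(Xt), batch):
                sel = order[start : start + batch]
                out, acts, masks = self._forward(Xt[sel], rng=rng)
                _, dout = self._loss_grad(out, yt[sel], wt[sel])
                delta = dout[:, None]
                gw = [None] * len(self.weights_)
                gb = [None] * len(self.biases_)
                for i in range(len(self.weights_) - 1, -1, -1):
                    gw[i] = acts[i].T @ delta + cfg.l2 * self.weights_[i]
                    gb[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.weights_[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                step += 1
                corr1 = 1 - beta1**step
                corr2 = 1 - beta2**step
                for i in range(len(self.weights_)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw[i] ** 2
                    self.weights_[i] -= cfg.lr * (m_w[i] / corr1) / (
                        np.sqrt(v_w[i] / corr2) + eps
                    )
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] ** 2
                    self.biases_[i] -= cfg.lr * (m_b[i] / corr1) / (
                        np.sqrt(v_b[i] / corr2) + eps
                    )

            if len(Xv):
                out_v, _, _ = self._forward(Xv)
                monitor, _ = self._loss_grad(out_v, yv, wv)
            else:
                out_t, _, _ = self._forward(Xt)
                monitor, _ = self._loss_grad(out_t, yt, wt)
            self.history_.append(monitor)
            if monitor < best - 1e-12:
                best = monitor
                best_params = (
                    [W.copy() for W in self.weights_],
                    [b.copy() for b in self.biases_],
                )
                stall = 0
            else:
                stall += 1
                if cfg.patience and stall >= cfg.patience:
                    break

        if best_params is not None:
            self.weights_, self.biases_ = best_params
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Raw network output (no dropout; deterministic)."""
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        out, _, _ = self._forward(X)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self.decision_function(X)
        if self.config.loss == "bce":
            return (out >= 0.0).astype(int)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.config.loss != "bce":
            raise RuntimeError("predict_proba requires a bce-loss network")
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    # -- serialization ---------------------------------------------------
    def to_arrays(self) -> dict[str, np.ndarray]:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_arrays(
        cls, arrays: dict[str, np.ndarray], config: NetworkConfig
    ) -> "MLP":
        model = cls(config)
        n_layers = sum(1 for k in arrays if k.startswith("W"))
        model.weights_ = [np.asarray(arrays[f"W{i}"]) for i in range(n_layers)]
        model.biases_ = [np.asarray(arrays[f"b{i}"]) for i in range(n_layers)]
        model.n_features_ = model.weights_[0].shape[0]
        return model
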