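"""Monte Carlo dropout Bayesian neural network for workload classification.

A fully-connected net (default 90 → 200 → 200 → 3, ReLU, dropout after each
hidden layer) trained with cross-entropy plus a KL penalty toward an
isotropic Gaussian prior N(0, 0.1²) on the weights; keeping dropout active
at prediction time and averaging stochastic forward passes approximates the
Bayesian predictive distribution (MC-dropout variational inference). The
optimizer is Adam (lr 0.001) with a reduce-on-plateau schedule.

For a fixed-form variational posterior implied by dropout, the KL term
reduces (up to a constant) to a squared-norm penalty ||W||² / (2σ_prior²);
with kl_weight = 0 the model is an ordinary dropout MLP.

Implemented in numpy: the architecture is small enough that full-batch
training is fast on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BNNConfig:
    hidden_sizes: tuple[int, ...] = (200, 200)
    dropout: float = 0.2
    prior_mean: float = 0.0
    prior_std: float = 0.1
    kl_weight: float = 0.05
    learning_rate: float = 1e-3
    epochs: int = 500  # desk-scale default; the reference setting is 10 000
    mc_samples: int = 50
    plateau_patience: int = 50
    plateau_factor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MCDropoutBNN:
    """Scikit-learn-style classifier interface (fit / predict / predict_proba)."""

    def __init__(self, config: BNNConfig | None = None, **overrides):
        cfg = config or BNNConfig()
        if overrides:
            cfg = BNNConfig(**{**cfg.__dict__, **overrides})
        cfg.validate()
        self.config = cfg
        self.weights_: list[np.ndarray] = []
        self.biases_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.loss_history_: list[float] = []

    # -- sklearn plumbing so clone() works inside cross-validation
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "MCDropoutBNN":
        if "config" in params:
            self.config = params["config"]
        return self

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Forward pass; dropout active when rng is given. Returns activations
        and dropout masks for backprop."""
        cfg = self.config
        acts = [X]
        masks = []
        h = X
        for li, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            if li < len(self.weights_) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and cfg.dropout > 0:
                    mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                    h = h * mask
                else:
                    mask = np.ones_like(h)
                masks.append(mask)
                acts.append(h)
            else:
                acts.append(z)
        return acts, masks

    def _kl(self) -> float:
        s2 = self.config.prior_std**2
        return sum(float(np.sum((W - self.config.prior_mean) ** 2)) for W in self.weights_) / (2 * s2)

    def fit(self, X, y) -> "MCDropoutBNN":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d_in = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need >= 2 classes")
        rng = np.random.default_rng(cfg.seed)

        sizes = [d_in, *cfg.hidden_sizes, k]
        self.weights_ = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases_ = [np.zeros(b) for b in sizes[1:]]

        onehot = np.zeros((n, k))
        onehot[np.arange(n), y_idx] = 1.0

        # Adam state
        mw = [np.zeros_like(W) for W in self.weights_]
        vw = [np.zeros_like(W) for W in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        best_loss, since_best = np.inf, 0
        self.loss_history_ = []

        for t in range(1, cfg.epochs + 1):
            acts, masks = self._forward(X, rng)
            probs = _softmax(acts[-1])
            ce = -float(np.mean(np.log(probs[np.arange(n), y_idx] + 1e-12)))
            loss = ce + cfg.kl_weight * self._kl() / n
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss}); config={cfg}")
            self.loss_history_.append(loss)

            # backprop
            delta = (probs - onehot) / n
            grads_W, grads_b = [], []
            for li in range(len(self.weights_) - 1, -1, -1):
                h_prev = acts[li]
                gW = h_prev.T @ delta + cfg.kl_weight * (
                    self.weights_[li] - cfg.prior_mean
                ) / (cfg.prior_std**2 * n)
                gb = delta.sum(axis=0)
                grads_W.insert(0, gW)
                grads_b.insert(0, gb)
                if li > 0:
                    delta = delta @ self.weights_[li].T
                    delta *= masks[li - 1]
                    delta[acts[li] <= 0] = 0.0

            for li in range(len(self.weights_)):
                mw[li] = b1 * mw[li] + (1 - b1) * grads_W[li]
                vw[li] = b2 * vw[li] + (1 - b2) * grads_W[li] ** 2
                mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
                vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
                mh = mw[li] / (1 - b1**t)
                vh = vw[li] / (1 - b2**t)
                self.weights_[li] -= lr * mh / (np.sqrt(vh) + eps)
                mhb = mb[li] / (1 - b1**t)
                vhb = vb[li] / (1 - b2**t)
                self.biases_[li] -= lr * mhb / (np.sqrt(vhb) + eps)

            if loss < best_loss - 1e-6:
                best_loss, since_best = loss, 0
            else:
                since_best += 1
                if since_best >= cfg.plateau_patience:
                    lr *= cfg.plateau_factor
                    since_best = 0
        return self

    def predict_proba(self, X, mc_samples: int | None = None,
                      seed: int | None = None) -> np.ndarray:
        """MC-averaged class probabilities over stochastic forward passes."""
        X = np.asarray(X, dtype=float)
        s = mc_samples if mc_samples is not None else self.config.mc_samples
        rng = np.random.default_rng(self.config.seed + 1 if seed is None else seed)
        if s <= 1 and self.config.dropout > 0:
            acts, _ = self._forward(X, rng)
            return _softmax(acts[-1])
        total = np.zeros((X.shape[0], len(self.classes_)))
        for _ in range(max(s, 1)):
            acts, _ = self._forward(X, rng if self.config.dropout > 0 else None)
            total += _softmax(acts[-1])
        return total / max(s, 1)

    def predict(self, X, mc_samples: int | None = None,
                seed: int | None = None) -> np.ndarray:
        probs = self.predict_proba(X, mc_samples=mc_samples, seed=seed)
        return self.classes_[np.argmax(probs, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_bnn(config: BNNConfig, features, labels) -> MCDropoutBNN:
    """Convenience wrapper: fit an MC-dropout network on standardized
    features and return the trained model."""
    model = MCDropoutBNN(config)
    return model.fit(features, labels)
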