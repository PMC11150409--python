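"""Stacked-autoencoder regressor for tabular environmental data.

The network has four stages: input, a stack of three autoencoder hidden
layers, a small neural-network regressor, and a single output. For input
dimension d the hidden widths follow a one-neuron-per-layer rule — two
compression layers (d-1, d-2) and one release layer (d-1) — and the
regressor head has one hidden layer of 32 units. Training is in two phases:

1. greedy layer-wise unsupervised pretraining — each autoencoder layer is
   trained to reconstruct its own input, initializing the encoder weights;
2. end-to-end supervised fine-tuning of encoder + head on squared error,
   with early stopping on a held-out validation split.

Inputs are z-score standardized with parameters stored at fit time and
reapplied at predict time; the target stays in its native units (mg/g).
Hidden units use a scaled tanh a*tanh(x/a) (default a=3), which is
quasi-linear over the range of standardized inputs yet bounded, so
reconstruction pretraining converges smoothly without saturation.
Everything is plain NumPy with full-batch Adam — the networks are tiny —
and every stage is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SaeConfig", "SaeRegressor", "sae_widths"]


def sae_widths(input_dim: int) -> tuple[int, int, int]:
    """Hidden widths (d-1, d-2, d-1) for input dimension d (requires d >= 4)."""
    if input_dim < 4:
        raise ValueError(f"input_dim must be >= 4, got {input_dim}")
    return (input_dim - 1, input_dim - 2, input_dim - 1)


@dataclass(frozen=True)
class SaeConfig:
    """Training hyperparameters (defaults tuned for tiny tabular networks)."""

    learning_rate: float = 0.01
    pretrain_lr: float = 0.02      # cosine-decayed to 0 over the pretrain epochs
    pretrain_epochs: int = 800
    finetune_epochs: int = 800
    act_scale: float = 3.0         # a in a*tanh(x/a): quasi-linear over standardized inputs
    patience: int = 80          # early-stopping patience, epochs
    val_frac: float = 0.15      # fine-tuning validation split
    head_hidden: int = 32
    seed: int = 0


class _Adam:
    """Full-batch Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_layer(rng: np.random.Generator, fan_in: int, fan_out: int):
    scale = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
    return rng.uniform(-scale, scale, (fan_in, fan_out)), np.zeros(fan_out)


class SaeRegressor:
    """Stacked autoencoder with a 32-unit regression head.

    Parameters
    ----------
    input_dim:
        Number of input features d (>= 4); hidden widths are derived as
        (d-1, d-2, d-1).
    config:
        :class:`SaeConfig` training hyperparameters.
    """

    def __init__(self, input_dim: int, config: SaeConfig | None = None):
        self.input_dim = int(input_dim)
        self.widths = sae_widths(input_dim)
        self.config = config or SaeConfig()
        rng = np.random.default_rng(self.config.seed)
        dims = [self.input_dim, *self.widths]
        self.enc_W: list[np.ndarray] = []
        self.enc_b: list[np.ndarray] = []
        for a, b in zip(dims[:-1], dims[1:]):
            W, bb = _init_layer(rng, a, b)
            self.enc_W.append(W)
            self.enc_b.append(bb)
        h = self.config.head_hidden
        self.head_W1, self.head_b1 = _init_layer(rng, self.widths[-1], h)
        self.head_W2, self.head_b2 = _init_layer(rng, h, 1)
        self._rng = rng
        self.x_mean: np.ndarray | None = None
        self.x_sd: np.ndarray | None = None
        self.pretrain_losses: list[list[float]] = []
        self.finetune_history: dict = {}

    # ------------------------------------------------------------------

    def _act(self, U: np.ndarray) -> np.ndarray:
        a = self.config.act_scale
        return a * np.tanh(U / a)

    def _dact(self, H: np.ndarray) -> np.ndarray:
        # derivative of a*tanh(u/a) expressed through the activation value
        return 1.0 - (H / self.config.act_scale) ** 2

    def _standardize(self, X: np.ndarray, fit: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if fit:
            self.x_mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.x_sd = sd
        if self.x_mean is None:
            raise RuntimeError("model not fitted: no standardization parameters")
        return (X - self.x_mean) / self.x_sd

    def _encode(self, Z: np.ndarray) -> np.ndarray:
        for W, b in zip(self.enc_W, self.enc_b):
            Z = self._act(Z @ W + b)
        return Z

    def pretrain(self, X: np.ndarray, standardized: bool = False) -> "SaeRegressor":
        """Greedy layer-wise reconstruction pretraining of the encoder stack.

        Each layer l is trained as a single-hidden-layer autoencoder
        (tanh code, linear decoder) reconstructing the activations of layer
        l-1; the learned encoder weights initialize the stack. Per-epoch
        reconstruction MSEs are logged in ``pretrain_losses``.
        """
        Z = np.asarray(X, dtype=float) if standardized else self._standardize(X, fit=True)
        if np.isnan(Z).any():
            raise ValueError("NaN in features")
        self.pretrain_losses = []
        for layer in range(len(self.enc_W)):
            W1 = self.enc_W[layer]
            b1 = self.enc_b[layer]
            W2, b2 = _init_layer(self._rng, W1.shape[1], W1.shape[0])
            opt = _Adam([W1, b1, W2, b2], self.config.pretrain_lr)
            losses = []
            n_ep = self.config.pretrain_epochs
            for e in range(n_ep):
                # cosine-decayed learning rate damps late-stage oscillation
                lr = self.config.pretrain_lr * 0.5 * (1 + np.cos(np.pi * e / n_ep))
                H = self._act(Z @ W1 + b1)
                R = H @ W2 + b2
                err = R - Z
                losses.append(float(np.mean(err**2)))
                gR = 2.0 * err / err.size
                gW2 = H.T @ gR
                gb2 = gR.sum(axis=0)
                gH = gR @ W2.T
                gA = gH * self._dact(H)
                gW1 = Z.T @ gA
                gb1 = gA.sum(axis=0)
                opt.step([gW1, gb1, gW2, gb2], lr=lr)
            H = self._act(Z @ W1 + b1)
            losses.append(float(np.mean((H @ W2 + b2 - Z) ** 2)))
            self.pretrain_losses.append(losses)
            Z = H
        return self

    # ------------------------------------------------------------------

    def _forward(self, Z: np.ndarray):
        acts = [Z]
        for W, b in zip(self.enc_W, self.enc_b):
            acts.append(self._act(acts[-1] @ W + b))
        H = self._act(acts[-1] @ self.head_W1 + self.head_b1)
        out = (H @ self.head_W2 + self.head_b2).ravel()
        return acts, H, out

    def _params(self):
        return [*self.enc_W, *self.enc_b,
                self.head_W1, self.head_b1, self.head_W2, self.head_b2]

    def finetune(self, X: np.ndarray, y: np.ndarray,
                 standardized: bool = False) -> "SaeRegressor":
        """End-to-end supervised fine-tuning on squared error with early
        stopping on a seeded validation split; the best-validation weights
        are restored at the end. Requires n >= 20 samples."""
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < 20:
            raise ValueError(f"too few samples for fine-tuning: n={len(y)} < 20")
        Z = np.asarray(X, dtype=float) if standardized else self._standardize(X, fit=self.x_mean is None)
        n = len(Z)
        rng = np.random.default_rng(self.config.seed + 1)
        n_val = int(round(self.config.val_frac * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if n_val < 2:
            val_idx = tr_idx

        params = self._params()
        opt = _Adam(params, self.config.learning_rate)
        best_val = np.inf
        best = [p.copy() for p in params]
        wait = 0
        train_losses, val_losses = [], []
        Zt, yt = Z[tr_idx], y[tr_idx]
        L = len(self.enc_W)
        for _ in range(self.config.finetune_epochs):
            acts, H, out = self._forward(Zt)
            err = out - yt
            train_losses.append(float(np.mean(err**2)))
            g_out = (2.0 * err / len(yt))[:, None]
            gW2 = H.T @ g_out
            gb2 = g_out.sum(axis=0)
            gH = g_out @ self.head_W2.T * self._dact(H)
            gW1 = acts[-1].T @ gH
            gb1 = gH.sum(axis=0)
            g_up = gH @ self.head_W1.T
            genc_W, genc_b = [None] * L, [None] * L
            for layer in range(L - 1, -1, -1):
                gA = g_up * self._dact(acts[layer + 1])
                genc_W[layer] = acts[layer].T @ gA
                genc_b[layer] = gA.sum(axis=0)
                g_up = gA @ self.enc_W[layer].T
            opt.step([*genc_W, *genc_b, gW1, gb1, gW2, gb2])

            _, _, val_out = self._forward(Z[val_idx])
            vloss = float(np.mean((val_out - y[val_idx]) ** 2))
            val_losses.append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best = [p.copy() for p in params]
                wait = 0
            else:
                wait += 1
                if wait >= self.config.patience:
                    break
        for p, b in zip(params, best):
            p[...] = b
        self.finetune_history = {
            "train_mse": train_losses, "val_mse": val_losses, "best_val_mse": best_val,
        }
        return self

    def fit(self, X: np.ndarray, y: np.ndarray, pretrain: bool = True) -> "SaeRegressor":
        """Standardize, (optionally) pretrain, then fine-tune."""
        Z = self._standardize(X, fit=True)
        if np.isnan(Z).any():
            raise ValueError("NaN in features")
        if pretrain:
            self.pretrain(Z, standardized=True)
        return self.finetune(Z, y, standardized=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass using the stored standardization."""
        Z = self._standardize(X, fit=False)
        return self._forward(Z)[2]
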