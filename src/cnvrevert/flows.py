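"""Conditional masked autoregressive flow (MAF) for density estimation.

A MAF stacks autoregressive affine transforms. Each transform is a MADE
(masked autoencoder for distribution estimation): a masked MLP that, for an
input vector ``x`` and a conditioning context ``c``, outputs a shift ``mu``
and log-scale ``alpha`` per dimension such that ``mu_i`` and ``alpha_i``
depend only on dimensions of ``x`` preceding ``i`` in the transform's
autoregressive order. The forward (density) direction maps data to the
standard-normal base,

    u_i = (x_i - mu_i(x_<i, c)) * exp(-alpha_i(x_<i, c)),

with log |det J| = -sum_i alpha_i. Stacking transforms with alternating
orders yields a flexible conditional density p(x | c) trained by maximum
likelihood. Sampling inverts each transform dimension-by-dimension in
autoregressive order.

Everything is plain NumPy: forward passes, hand-derived backpropagation,
and an Adam optimizer with early stopping on a validation split. Training
is deterministic given the data and the seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConditionalMAF", "MADE", "TrainingLog"]

_LOG2PI = np.log(2.0 * np.pi)
_ALPHA_CAP = 5.0  # soft bound on log-scales, keeps exp() well-conditioned


class MADE:
    """One conditional masked autoregressive transform (Gaussian MADE).

    Parameters
    ----------
    dim : input dimensionality.
    context_dim : dimensionality of the conditioning vector (unmasked).
    hidden : hidden-layer width.
    order : permutation of ``1..dim`` assigning each input its autoregressive
        degree; alternating orders between stacked transforms lets every
        dimension condition on every other across the stack.
    rng : seeded generator for weight initialization.
    """

    def __init__(
        self,
        dim: int,
        context_dim: int,
        hidden: int,
        order: np.ndarray,
        rng: np.random.Generator,
    ) -> None:
        self.dim = dim
        self.context_dim = context_dim
        self.hidden = hidden
        self.order = np.asarray(order, dtype=int)  # degrees in 1..dim
        if sorted(self.order.tolist()) != list(range(1, dim + 1)):
            raise ValueError("order must be a permutation of 1..dim")
        m_hidden = (np.arange(hidden) % max(dim - 1, 1)) + 1
        self.mask1 = (m_hidden[:, None] >= self.order[None, :]).astype(float)
        self.mask2 = (self.order[:, None] > m_hidden[None, :]).astype(float)

        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), size=shape)

        self.params = {
            "W1": init((hidden, dim), dim) * self.mask1,
            "V1": init((hidden, context_dim), context_dim),
            "b1": np.zeros(hidden),
            "Wm": init((dim, hidden), hidden) * self.mask2,
            "Vm": init((dim, context_dim), context_dim),
            "bm": np.zeros(dim),
            "Wa": init((dim, hidden), hidden) * self.mask2 * 0.01,
            "Va": init((dim, context_dim), context_dim) * 0.01,
            "ba": np.zeros(dim),
        }

    def forward(self, x: np.ndarray, c: np.ndarray):
        """Compute (mu, alpha) and a cache for backprop. x: (B, D), c: (B, C)."""
        p = self.params
        pre = x @ (p["W1"] * self.mask1).T + c @ p["V1"].T + p["b1"]
        h = np.tanh(pre)
        mu = h @ (p["Wm"] * self.mask2).T + c @ p["Vm"].T + p["bm"]
        raw = h @ (p["Wa"] * self.mask2).T + c @ p["Va"].T + p["ba"]
        alpha = _ALPHA_CAP * np.tanh(raw / _ALPHA_CAP)
        cache = (x, c, h, alpha)
        return mu, alpha, cache

    def backward(self, gmu: np.ndarray, galpha: np.ndarray, cache):
        """Backprop gradients of the loss wrt (mu, alpha) through the net.

        Returns (grads dict matching ``params``, dL/dx).
        """
        x, c, h, alpha = cache
        p = self.params
        graw = galpha * (1.0 - (alpha / _ALPHA_CAP) ** 2)
        grads = {
            "Wm": (gmu.T @ h) * self.mask2,
            "Vm": gmu.T @ c,
            "bm": gmu.sum(axis=0),
            "Wa": (graw.T @ h) * self.mask2,
            "Va": graw.T @ c,
            "ba": graw.sum(axis=0),
        }
        dh = gmu @ (p["Wm"] * self.mask2) + graw @ (p["Wa"] * self.mask2)
        dpre = dh * (1.0 - h**2)
        grads["W1"] = (dpre.T @ x) * self.mask1
        grads["V1"] = dpre.T @ c
        grads["b1"] = dpre.sum(axis=0)
        dx = dpre @ (p["W1"] * self.mask1)
        return grads, dx

    def invert(self, u: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Solve u = (x - mu(x,c)) exp(-alpha(x,c)) for x, sequentially by degree."""
        x = np.zeros_like(u)
        for d in range(1, self.dim + 1):
            mu, alpha, _ = self.forward(x, c)
            idx = self.order == d
            x[:, idx] = u[:, idx] * np.exp(alpha[:, idx]) + mu[:, idx]
        return x


@dataclass
class TrainingLog:
    """Per-epoch train/validation negative log-likelihoods."""

    train_nll: list[float] = field(default_factory=list)
    val_nll: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_nll: float = np.inf


class ConditionalMAF:
    """Stack of conditional MADE transforms trained by maximum likelihood."""

    def __init__(
        self,
        dim: int,
        context_dim: int,
        n_transforms: int = 5,
        hidden: int = 50,
        seed: int = 0,
        base: str = "normal",
    ) -> None:
        """``base`` is the latent distribution: "normal" or "logistic". A
        logistic base matches the exponential tails of logit-transformed
        uniform densities, which a Gaussian base systematically thins."""
        if base not in ("normal", "logistic"):
            raise ValueError("base must be 'normal' or 'logistic'")
        self.base = base
        self.dim = dim
        self.context_dim = context_dim
        rng = np.random.default_rng(seed)
        base = np.arange(1, dim + 1)
        self.transforms = [
            MADE(dim, context_dim, hidden, base if k % 2 == 0 else base[::-1], rng)
            for k in range(n_transforms)
        ]
        self.log = TrainingLog()

    # ------------------------------------------------------------------ density

    def _forward_chain(self, x: np.ndarray, c: np.ndarray):
        u = x
        caches = []
        logdet = np.zeros(x.shape[0])
        for t in self.transforms:
            mu, alpha, cache = t.forward(u, c)
            u = (u - mu) * np.exp(-alpha)
            caches.append((cache, alpha, u))
            logdet -= alpha.sum(axis=1)
        return u, logdet, caches

    def _base_logpdf(self, u: np.ndarray) -> np.ndarray:
        if self.base == "normal":
            return -0.5 * (u**2).sum(axis=1) - 0.5 * self.dim * _LOG2PI
        # standard logistic: log f(u) = -u - 2 softplus(-u)
        return (-u - 2.0 * np.logaddexp(0.0, -u)).sum(axis=1)

    def _base_nll_grad(self, u: np.ndarray) -> np.ndarray:
        """d(-log f(u))/du per element."""
        if self.base == "normal":
            return u
        return np.tanh(u / 2.0)

    def log_prob(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Log-density of each row of x under p(x | c)."""
        u, logdet, _ = self._forward_chain(np.atleast_2d(x), np.atleast_2d(c))
        return self._base_logpdf(u) + logdet

    def sample(self, n: int, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples conditioned on a single context vector c."""
        c = np.broadcast_to(np.atleast_2d(c), (n, self.context_dim))
        if self.base == "normal":
            x = rng.standard_normal((n, self.dim))
        else:
            x = rng.logistic(size=(n, self.dim))
        for t in reversed(self.transforms):
            x = t.invert(x, c)
        return x

    # ----------------------------------------------------------------- training

    def _loss_and_grads(self, x: np.ndarray, c: np.ndarray):
        B = x.shape[0]
        u, logdet, caches = self._forward_chain(x, c)
        nll = float(np.mean(-self._base_logpdf(u) - logdet))
        g = self._base_nll_grad(u) / B  # dL/du_K
        all_grads = [None] * len(self.transforms)
        for k in range(len(self.transforms) - 1, -1, -1):
            cache, alpha, u_out = caches[k]
            scale = np.exp(-alpha)
            galpha = -g * u_out + 1.0 / B  # logdet contributes +alpha to NLL
            gmu = -g * scale
            grads, dx = self.transforms[k].backward(gmu, galpha, cache)
            all_grads[k] = grads
            g = g * scale + dx
        return nll, all_grads

    def fit(
        self,
        x: np.ndarray,
        c: np.ndarray,
        rng: np.random.Generator,
        batch_size: int = 100,
        lr: float = 1e-3,
        max_epochs: int = 400,
        patience: int = 20,
        val_frac: float = 0.1,
        val_data: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> TrainingLog:
        """Train by minibatch Adam with early stopping on a validation split.

        Keeps the parameters from the epoch with the lowest validation NLL.
        ``val_data`` supplies an explicit held-out (x, c) pair — callers with
        augmented/replicated rows must hold out at the level of the original
        data points to keep the validation estimate honest. Without it a
        random ``val_frac`` row split is used. Raises if the data are too few
        to hold out a validation set.
        """
        n = x.shape[0]
        if val_data is not None:
            xtr, ctr = x, c
            xva, cva = val_data
            if n < batch_size or len(xva) < 1:
                raise ValueError(
                    f"need at least {batch_size} training simulations and one "
                    f"validation point, got {n} and {len(xva)}"
                )
        else:
            n_val = int(round(n * val_frac))
            if n_val < 1 or n - n_val < batch_size:
                raise ValueError(
                    f"need at least {batch_size + max(1, int(1 / max(val_frac, 1e-9)))} "
                    f"simulations to split train/validation, got {n}"
                )
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            xtr, ctr = x[tr_idx], c[tr_idx]
            xva, cva = x[val_idx], c[val_idx]

        # Adam state
        m = [{k: np.zeros_like(v) for k, v in t.params.items()} for t in self.transforms]
        v = [{k: np.zeros_like(p) for k, p in t.params.items()} for t in self.transforms]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = [{k: p.copy() for k, p in t.params.items()} for t in self.transforms]
        log = TrainingLog()
        log.val_nll.append(float(np.mean(-self.log_prob(xva, cva))))
        log.best_val_nll = log.val_nll[0]
        log.best_epoch = 0
        since_best = 0
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(len(xtr))
            epoch_nll = 0.0
            n_batches = 0
            for start in range(0, len(xtr) - batch_size + 1, batch_size):
                idx = order[start : start + batch_size]
                nll, grads = self._loss_and_grads(xtr[idx], ctr[idx])
                epoch_nll += nll
                n_batches += 1
                step += 1
                for t, mt, vt, gt in zip(self.transforms, m, v, grads):
                    for k in t.params:
                        g = gt[k]
                        mt[k] = b1 * mt[k] + (1 - b1) * g
                        vt[k] = b2 * vt[k] + (1 - b2) * g**2
                        mhat = mt[k] / (1 - b1**step)
                        vhat = vt[k] / (1 - b2**step)
                        t.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            log.train_nll.append(epoch_nll / max(n_batches, 1))
            val_nll = float(np.mean(-self.log_prob(xva, cva)))
            log.val_nll.append(val_nll)
            if val_nll < log.best_val_nll - 1e-6:
                log.best_val_nll = val_nll
                log.best_epoch = epoch
                best = [{k: p.copy() for k, p in t.params.items()} for t in self.transforms]
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        for t, bp in zip(self.transforms, best):
            t.params = bp
        self.log = log
        return log
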