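"""Minimal feed-forward networks with analytic input gradients.

Attribution integrates the gradient of the prediction with respect to the
*input* along a path, so the network core exposes vector-Jacobian products
with respect to both parameters (for training) and inputs (for attribution).
Hidden layers use tanh so the prediction surface is smooth everywhere; the
trapezoidal integration diagnostics in :mod:`gradpath.attribution` rely on
that smoothness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FeedForward", "adam_fit"]


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _dtanh(a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value
    return 1.0 - a * a


class FeedForward:
    """A dense tanh network with a linear output layer.

    Parameters
    ----------
    sizes
        Layer widths ``[in, hidden..., out]``.
    rng
        Seeded generator for Glorot-style initialization.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output layer sizes")
        self.sizes = list(sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_in(self) -> int:
        return self.sizes[0]

    @property
    def n_out(self) -> int:
        return self.sizes[-1]

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return outputs and the list of layer activations (A_0 .. A_L)."""
        A = np.asarray(X, dtype=float)
        acts = [A]
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            Z = A @ W + b
            A = Z if i == last else _tanh(Z)
            acts.append(A)
        return A, acts

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def vjp(
        self, acts: list[np.ndarray], V: np.ndarray, with_params: bool = False
    ):
        """Vector-Jacobian product: propagate upstream cotangent ``V``.

        Returns ``dX`` of shape (n, n_in); when ``with_params`` also returns
        per-parameter gradients (summed over the batch).
        """
        delta = np.asarray(V, dtype=float)
        grads_W, grads_b = [], []
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            if i != last:
                delta = delta * _dtanh(acts[i + 1])
            if with_params:
                grads_W.append(acts[i].T @ delta)
                grads_b.append(delta.sum(axis=0))
            delta = delta @ self.weights[i].T
        if with_params:
            return delta, grads_W[::-1], grads_b[::-1]
        return delta

    def input_gradient(self, X: np.ndarray, output: int = 0) -> np.ndarray:
        """Gradient of the selected scalar output w.r.t. each input row."""
        Y, acts = self.forward(np.atleast_2d(X))
        V = np.zeros_like(Y)
        V[:, output] = 1.0
        return self.vjp(acts, V)

    # -- parameter plumbing --------------------------------------------------

    def get_params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def state_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "weights": [W.copy() for W in self.weights],
            "biases": [b.copy() for b in self.biases],
        }

    @classmethod
    def from_state(cls, state: dict) -> "FeedForward":
        net = cls(state["sizes"], np.random.default_rng(0))
        net.weights = [np.asarray(W, dtype=float) for W in state["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in state["biases"]]
        return net


def adam_fit(
    params: list[np.ndarray],
    grad_fn,
    n_epochs: int,
    lr: float = 1e-2,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> float:
    """Full-batch Adam on a list of parameter arrays, updated in place.

    ``grad_fn()`` must return ``(loss, grads)`` with grads aligned to
    ``params``. Returns the final loss. Raises if the loss goes non-finite.
    """
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    loss = np.inf
    for t in range(1, n_epochs + 1):
        loss, grads = grad_fn()
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged: loss={loss!r}")
        for p, g, mi, vi in zip(params, grads, m, v):
            mi += (1 - beta1) * (g - mi)
            vi += (1 - beta2) * (g * g - vi)
            mhat = mi / (1 - beta1**t)
            vhat = vi / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
    return float(loss)
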