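"""Prediction-function and encoder/decoder contracts plus reference models.

The attribution machinery needs only two things from a model: a scalar
prediction ``F(x)`` over a p-dimensional feature space and its gradient
``dF/dx``. :class:`PredictionFunction` is that contract; the hidden-space
paths additionally need a :class:`LatentCodec` (encoder/decoder pair).

Reference implementations are small tanh networks trained on synthetic data:
an autoencoder for the codec and a predictor whose first stage is the frozen
encoder, so attribution can run in both the original and latent spaces on a
single combined network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from ._mlp import FeedForward, adam_fit

__all__ = [
    "PredictionFunction",
    "FunctionModel",
    "LatentCodec",
    "IdentityCodec",
    "FunctionCodec",
    "MLPCodec",
    "EncoderPredictor",
    "ModelConfig",
    "SplicingTargets",
    "gradient",
    "train_autoencoder",
    "train_reference_models",
    "latent_stability",
    "splicing_targets",
    "save_models",
    "load_models",
]


class PredictionFunction:
    """Scalar differentiable prediction over a p-dimensional feature space."""

    p: int

    def evaluate(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # batch defaults; network models override with vectorized versions
    def evaluate_batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.evaluate(row) for row in np.atleast_2d(X)])

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        return np.stack([self.gradient(row) for row in np.atleast_2d(X)])


class FunctionModel(PredictionFunction):
    """Wrap plain callables as a prediction function.

    When no analytic gradient is supplied, falls back to central finite
    differences with per-coordinate step ``h_j = 1e-5 * max(1, |x_j|)``.
    """

    def __init__(self, f: Callable, p: int, grad: Callable | None = None):
        self.f = f
        self.p = int(p)
        self._grad = grad

    def evaluate(self, x: np.ndarray) -> float:
        return float(self.f(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._grad is not None:
            g = np.asarray(self._grad(x), dtype=float)
        else:
            g = np.empty(self.p)
            for j in range(self.p):
                h = 1e-5 * max(1.0, abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                g[j] = (self.f(xp) - self.f(xm)) / (2.0 * h)
        bad = np.flatnonzero(~np.isfinite(g))
        if bad.size:
            raise FloatingPointError(
                f"non-finite gradient at coordinate(s) {bad.tolist()}"
            )
        return g


def gradient(F: PredictionFunction, x: np.ndarray) -> np.ndarray:
    """Gradient of ``F`` at ``x`` (analytic, or finite-difference fallback)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input point must be finite")
    return F.gradient(x)


class LatentCodec:
    """Encoder/decoder pair between feature space (dim p) and latent (dim q)."""

    p: int
    q: int

    def encode(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def decode(self, Z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def reconstruction_error(self, X: np.ndarray) -> np.ndarray:
        """Per-point Euclidean reconstruction error."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        R = self.decode(self.encode(X))
        return np.linalg.norm(R - X, axis=1)


class IdentityCodec(LatentCodec):
    """Degenerate codec with q = p; useful for collapsing latent paths."""

    def __init__(self, p: int):
        self.p = self.q = int(p)

    def encode(self, X):
        return np.atleast_2d(np.asarray(X, dtype=float))

    def decode(self, Z):
        return np.atleast_2d(np.asarray(Z, dtype=float))


class FunctionCodec(LatentCodec):
    """Codec from arbitrary encode/decode callables (row-wise batched)."""

    def __init__(self, encode: Callable, decode: Callable, p: int, q: int):
        self._enc, self._dec = encode, decode
        self.p, self.q = int(p), int(q)

    def encode(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.atleast_2d(np.asarray([self._enc(row) for row in X], dtype=float))

    def decode(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return np.atleast_2d(np.asarray([self._dec(row) for row in Z], dtype=float))


class MLPCodec(LatentCodec):
    """Autoencoder codec backed by two tanh networks."""

    def __init__(self, encoder: FeedForward, decoder: FeedForward):
        if encoder.n_out != decoder.n_in:
            raise ValueError("encoder output and decoder input dims differ")
        self.encoder = encoder
        self.decoder = decoder
        self.p = encoder.n_in
        self.q = encoder.n_out

    def encode(self, X):
        return self.encoder(np.atleast_2d(np.asarray(X, dtype=float)))

    def decode(self, Z):
        return self.decoder(np.atleast_2d(np.asarray(Z, dtype=float)))


class EncoderPredictor(PredictionFunction):
    """Predictor whose first stage is a frozen encoder.

    ``F(x) = head(encode(x))[target]``; gradients chain through both stages
    analytically. The combined network is what attribution paths interrogate,
    in either space.
    """

    def __init__(self, codec: MLPCodec, head: FeedForward, target: int = 0,
                 target_names: Sequence[str] | None = None):
        if head.n_in != codec.q:
            raise ValueError("head input dim must equal latent dim q")
        self.codec = codec
        self.head = head
        self.target = int(target)
        self.target_names = list(target_names) if target_names else None
        self.p = codec.p

    def select_target(self, name_or_index) -> None:
        if isinstance(name_or_index, str):
            if not self.target_names or name_or_index not in self.target_names:
                raise KeyError(f"unknown target {name_or_index!r}")
            self.target = self.target_names.index(name_or_index)
        else:
            self.target = int(name_or_index)

    def evaluate_batch(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.head(self.codec.encoder(X))[:, self.target]

    def gradient_batch(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z, enc_acts = self.codec.encoder.forward(X)
        Y, head_acts = self.head.forward(Z)
        V = np.zeros_like(Y)
        V[:, self.target] = 1.0
        dZ = self.head.vjp(head_acts, V)
        return self.codec.encoder.vjp(enc_acts, dZ)

    # latent-space view of the same scalar (used by latent paths' diagnostics)
    def evaluate_latent(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.head(Z)[:, self.target]

    def evaluate(self, x):
        return float(self.evaluate_batch(x)[0])

    def gradient(self, x):
        return self.gradient_batch(x)[0]


@dataclass
class ModelConfig:
    """Hyperparameters for the reference autoencoder + predictor pair."""

    q: int = 8
    ae_hidden: tuple[int, ...] = (32,)
    head_hidden: tuple[int, ...] = (16,)
    ae_epochs: int = 400
    head_epochs: int = 400
    lr: float = 1e-2
    n_targets: int = 1
    target_names: tuple[str, ...] | None = None
    loss: str = "logistic"  # or "mse" for regression targets

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "ae_hidden": list(self.ae_hidden),
            "head_hidden": list(self.head_hidden),
            "ae_epochs": self.ae_epochs,
            "head_epochs": self.head_epochs,
            "lr": self.lr,
            "n_targets": self.n_targets,
            "target_names": list(self.target_names) if self.target_names else None,
            "loss": self.loss,
        }


def train_autoencoder(
    X: np.ndarray, q: int, hidden: Sequence[int] = (32,),
    n_epochs: int = 400, lr: float = 1e-2, seed: int = 0,
) -> MLPCodec:
    """Train a mean-squared-error autoencoder; returns the codec."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if q >= p:
        raise ValueError(f"latent dimension q={q} must compress (q < p={p})")
    rng = np.random.default_rng(seed)
    enc = FeedForward([p, *hidden, q], rng)
    dec = FeedForward([q, *hidden[::-1], p], rng)
    params = enc.get_params() + dec.get_params()
    n_enc = len(enc.get_params())

    def grad_fn():
        Z, enc_acts = enc.forward(X)
        R, dec_acts = dec.forward(Z)
        diff = R - X
        loss = float(np.mean(diff * diff))
        V = 2.0 * diff / diff.size
        dZ, dec_gW, dec_gb = dec.vjp(dec_acts, V, with_params=True)
        _, enc_gW, enc_gb = enc.vjp(enc_acts, dZ, with_params=True)
        grads = enc_gW + enc_gb + dec_gW + dec_gb
        # align grads to params ordering (weights then biases per net)
        return loss, grads

    # params ordering is weights+biases for enc then dec; grads built to match
    adam_fit(params, grad_fn, n_epochs, lr=lr)
    return MLPCodec(enc, dec)


def train_reference_models(
    X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[MLPCodec, EncoderPredictor]:
    """Autoencoder + frozen-encoder predictor trained on labeled data.

    The codec is fit for reconstruction on all samples; the predictor head is
    then fit on the (frozen) latent embedding. With ``loss='logistic'`` the
    head output is a class logit; with ``'mse'`` it regresses the given
    target column(s).
    """
    config = config or ModelConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if config.loss == "logistic" and len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    codec = train_autoencoder(
        X, config.q, config.ae_hidden, config.ae_epochs, config.lr, seed
    )
    rng = np.random.default_rng(seed + 1)
    head = FeedForward([codec.q, *config.head_hidden, max(config.n_targets, y.shape[1])], rng)
    Z = codec.encode(X)  # frozen encoder: computed once

    def grad_fn():
        Y, acts = head.forward(Z)
        if config.loss == "logistic":
            P = 1.0 / (1.0 + np.exp(-Y))
            eps = 1e-12
            loss = float(-np.mean(y * np.log(P + eps) + (1 - y) * np.log(1 - P + eps)))
            V = (P - y) / y.size
        else:
            diff = Y - y
            loss = float(np.mean(diff * diff))
            V = 2.0 * diff / diff.size
        _, gW, gb = head.vjp(acts, V, with_params=True)
        return loss, gW + gb

    adam_fit(head.get_params(), grad_fn, config.head_epochs, lr=config.lr)
    predictor = EncoderPredictor(codec, head, target=0,
                                 target_names=config.target_names)
    return codec, predictor


def latent_stability(
    codecs: Sequence[LatentCodec], points: np.ndarray
) -> np.ndarray:
    """Pairwise Spearman rank correlation of latent pairwise distances.

    Entry (a, b) correlates the n(n-1)/2 Euclidean distances among the
    encoded points under codec a with those under codec b; rank-preserving
    re-embeddings therefore score 1 regardless of scale.
    """
    if len(codecs) < 2:
        raise ValueError("need at least 2 codecs")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points")
    dists = [pdist(np.atleast_2d(c.encode(points))) for c in codecs]
    k = len(codecs)
    M = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            if np.ptp(dists[a]) == 0 or np.ptp(dists[b]) == 0:
                import warnings

                warnings.warn(
                    "constant distance vector; rank correlation undefined",
                    stacklevel=2,
                )
                M[a, b] = M[b, a] = np.nan
                continue
            rho = spearmanr(dists[a], dists[b]).statistic
            M[a, b] = M[b, a] = rho
    return M


@dataclass
class SplicingTargets:
    """Targets of a splicing-code model for one event/condition pair.

    ``t_psi`` is the expected inclusion level (PSI) in [0, 1];
    ``t_dpsi_inc``/``t_dpsi_exc`` capture differential inclusion/exclusion
    magnitude between two conditions, floored at a small epsilon so
    non-changing events carry small symmetric targets.
    """

    t_psi: float
    t_dpsi_inc: float
    t_dpsi_exc: float
    epsilon: float

    def __post_init__(self):
        assert 0.0 <= self.t_psi <= 1.0
        assert self.t_dpsi_inc >= 0 and self.t_dpsi_exc >= 0


def splicing_targets(
    e_psi: float, e_dpsi: float, epsilon: float | None = None,
    seed: int | None = None,
) -> SplicingTargets:
    """Compute splicing-code targets from expected PSI and delta-PSI.

    t_psi = E[PSI]; t_dpsi_inc = |max(eps, E[dPSI])|;
    t_dpsi_exc = |min(-eps, E[dPSI])|, with eps ~ U(0.01, 0.03) when not
    given. The epsilon floor gives non-changing events small symmetric
    differential targets instead of exact zeros.
    """
    if not 0.0 <= e_psi <= 1.0:
        raise ValueError("e_psi must lie in [0, 1]")
    if not -1.0 <= e_dpsi <= 1.0:
        raise ValueError("e_dpsi must lie in [-1, 1]")
    if epsilon is None:
        epsilon = float(np.random.default_rng(seed).uniform(0.01, 0.03))
    if not 0.01 <= epsilon <= 0.03:
        raise ValueError("epsilon must lie in [0.01, 0.03]")
    return SplicingTargets(
        t_psi=float(e_psi),
        t_dpsi_inc=abs(max(epsilon, e_dpsi)),
        t_dpsi_exc=abs(min(-epsilon, e_dpsi)),
        epsilon=float(epsilon),
    )


# -- checkpointing -----------------------------------------------------------


def save_models(path: str | Path, codec: MLPCodec,
                predictor: EncoderPredictor | None = None,
                seed: int | None = None, config: ModelConfig | None = None) -> None:
    """Save codec (+ optional predictor) as .npz with a JSON sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for tag, net in [("enc", codec.encoder), ("dec", codec.decoder)] + (
        [("head", predictor.head)] if predictor else []
    ):
        for i, W in enumerate(net.weights):
            arrays[f"{tag}_W{i}"] = W
        for i, b in enumerate(net.biases):
            arrays[f"{tag}_b{i}"] = b
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "p": codec.p,
        "q": codec.q,
        "seed": seed,
        "enc_sizes": codec.encoder.sizes,
        "dec_sizes": codec.decoder.sizes,
        "head_sizes": predictor.head.sizes if predictor else None,
        "target_names": predictor.target_names if predictor else None,
        "config": config.to_dict() if config else None,
    }
    meta["config_hash"] = hex(abs(hash(json.dumps(meta, sort_keys=True))))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_models(path: str | Path) -> tuple[MLPCodec, EncoderPredictor | None]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))

    def build(tag: str, sizes: list[int]) -> FeedForward:
        state = {
            "sizes": sizes,
            "weights": [data[f"{tag}_W{i}"] for i in range(len(sizes) - 1)],
            "biases": [data[f"{tag}_b{i}"] for i in range(len(sizes) - 1)],
        }
        return FeedForward.from_state(state)

    codec = MLPCodec(build("enc", meta["enc_sizes"]), build("dec", meta["dec_sizes"]))
    predictor = None
    if meta.get("head_sizes"):
        predictor = EncoderPredictor(
            codec, build("head", meta["head_sizes"]),
            target_names=meta.get("target_names"),
        )
    return codec, predictor
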