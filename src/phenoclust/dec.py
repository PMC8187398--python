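"""Deep embedded clustering in an autoencoder latent space.

A plain NumPy multilayer-perceptron autoencoder is pretrained on mean squared
reconstruction error; cluster centroids are initialized by k-means on the
embeddings; training then alternates Student's-t soft assignment with
self-training against a sharpened target distribution under KL-divergence
loss, updating both the encoder and the centroids. Runs on one CPU at desk
scale with no deep-learning framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import ClusteringResult, kmeans_cluster
from .preprocess import FeatureMatrix

__all__ = [
    "AutoencoderSpec",
    "Autoencoder",
    "DECModel",
    "TrainState",
    "pretrain_autoencoder",
    "init_centroids",
    "soft_assign",
    "target_distribution",
    "kl_loss",
    "train_dec",
    "run_dec_ensemble",
]


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and optimization settings for the MLP autoencoder."""

    layer_widths: tuple[int, ...] = (64, 32, 10)  # hidden widths ending at d_z
    activation: str = "relu"
    pretrain_epochs: int = 100
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 1 or any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if self.layer_widths[-1] < 2:
            raise ValueError("embedding dimension d_z must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def d_z(self) -> int:
        return self.layer_widths[-1]


class _MLP:
    """Fully-connected net; ReLU on hidden layers, linear output."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 activation: str = "relu"):
        self.activation = activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.vW = [np.zeros_like(w) for w in self.W]
        self.vb = [np.zeros_like(b) for b in self.b]

    def _act(self, h: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return np.maximum(h, 0.0)
        if self.activation == "linear":
            return h
        raise ValueError(f"unknown activation {self.activation!r}")

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        cache = [X]
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i != last:
                h = self._act(h)
            cache.append(h)
        return h, cache

    def backward(self, cache: list[np.ndarray], d_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. parameters and the input."""
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        last = len(self.W) - 1
        delta = d_out
        for i in range(last, -1, -1):
            if i != last and self.activation == "relu":
                delta = delta * (cache[i + 1] > 0)
            gW[i] = cache[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return gW, gb, delta

    def sgd_step(self, gW, gb, lr: float, momentum: float) -> None:
        for i in range(len(self.W)):
            self.vW[i] = momentum * self.vW[i] - lr * gW[i]
            self.vb[i] = momentum * self.vb[i] - lr * gb[i]
            self.W[i] += self.vW[i]
            self.b[i] += self.vb[i]


@dataclass
class Autoencoder:
    encoder: _MLP
    decoder: _MLP
    spec: AutoencoderSpec
    loss_trace: list[float] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        z, _ = self.encoder.forward(X)
        return z

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.decoder.forward(self.encode(X))
        return out


@dataclass
class DECModel:
    autoencoder: Autoencoder
    centroids: np.ndarray  # k x d_z
    alpha: float = 1.0
    k: int = 2

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    def predict_soft(self, X: np.ndarray) -> np.ndarray:
        return soft_assign(self.autoencoder.encode(X), self.centroids, self.alpha)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_soft(X), axis=1)


@dataclass
class TrainState:
    iteration: int
    kl_loss: float
    label_change_fraction: float
    max_iter: int = 8000
    tol: float = 0.01


def _as_matrix(fm) -> np.ndarray:
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


def pretrain_autoencoder(fm, spec: AutoencoderSpec) -> Autoencoder:
    """Minimize mean squared reconstruction error with minibatch SGD."""
    X = _as_matrix(fm)
    n, p = X.shape
    rng = np.random.default_rng(spec.seed)
    widths = [p, *spec.layer_widths]
    encoder = _MLP(widths, rng, activation=spec.activation)
    decoder = _MLP(widths[::-1], rng, activation=spec.activation)
    ae = Autoencoder(encoder, decoder, spec)
    bs = min(spec.batch_size, n)
    for _ in range(spec.pretrain_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = X[idx]
            z, enc_cache = encoder.forward(xb)
            xhat, dec_cache = decoder.forward(z)
            resid = xhat - xb
            epoch_loss += float((resid**2).sum())
            d_out = 2.0 * resid / (xb.shape[0] * p)
            gWd, gbd, dz = decoder.backward(dec_cache, d_out)
            gWe, gbe, _ = encoder.backward(enc_cache, dz)
            decoder.sgd_step(gWd, gbd, spec.learning_rate, spec.momentum)
            encoder.sgd_step(gWe, gbe, spec.learning_rate, spec.momentum)
        ae.loss_trace.append(epoch_loss / (n * p))
    return ae


def init_centroids(Z: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Centroids from k-means on the embeddings (delegates to the baseline)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < k:
        raise ValueError("need n >= k embeddings")
    result = kmeans_cluster(Z, k=k, seed=seed)
    return np.asarray(result.diagnostics["centers"], dtype=float)


def soft_assign(Z: np.ndarray, centroids: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student's-t kernel similarities, normalized per row.

    q_ij = (1 + ||z_i - mu_j||^2 / alpha)^(-(alpha+1)/2), row-normalized.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    mu = np.atleast_2d(np.asarray(centroids, dtype=float))
    d2 = ((Z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    w = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return w / w.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target: p_ij proportional to q_ij^2 / cluster frequency."""
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    w = Q**2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """Sum_i sum_j p log(p/q), with 0 log 0 := 0. Errors if q=0 where p>0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have equal shapes")
    mask = P > 0
    if np.any(Q[mask] == 0):
        raise ValueError("q_ij = 0 where p_ij > 0: KL divergence undefined")
    out = np.zeros_like(P)
    out[mask] = P[mask] * np.log(P[mask] / Q[mask])
    return float(out.sum())


def _check_rows(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    rs = M.sum(axis=1)
    if np.max(np.abs(rs - 1.0)) > tol:
        raise AssertionError(f"{name} rows do not sum to 1 (max err {np.max(np.abs(rs-1)):.2e})")


def train_dec(
    fm,
    k: int,
    spec: AutoencoderSpec | None = None,
    max_iter: int = 8000,
    tol: float = 0.01,
    update_interval: int = 140,
    alpha: float = 1.0,
    dec_learning_rate: float | None = None,
) -> tuple[DECModel, ClusteringResult, list[TrainState]]:
    """Pretrain, initialize centroids, then KL self-train for up to ``max_iter`` batches.

    Every ``update_interval`` batch steps the full-data soft assignment Q is
    recomputed, the target P is refreshed, and training stops once the
    fraction of points whose hard assignment changed since the previous
    refresh falls below ``tol``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    spec = spec or AutoencoderSpec()
    X = _as_matrix(fm)
    n = X.shape[0]
    rng = np.random.default_rng(spec.seed)
    ae = pretrain_autoencoder(X, spec)
    encoder = ae.encoder
    Z = ae.encode(X)
    centroids = init_centroids(Z, k, seed=spec.seed)
    lr = dec_learning_rate if dec_learning_rate is not None else spec.learning_rate
    mom = spec.momentum
    v_mu = np.zeros_like(centroids)

    Q = soft_assign(Z, centroids, alpha)
    _check_rows(Q, "Q")
    P = target_distribution(Q)
    _check_rows(P, "P")
    prev_labels = np.argmax(Q, axis=1)
    trace: list[TrainState] = [
        TrainState(0, kl_loss(P, Q), 1.0, max_iter=max_iter, tol=tol)
    ]

    bs = min(spec.batch_size, n)
    order = rng.permutation(n)
    cursor = 0
    it = 0
    while it < max_iter:
        it += 1
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + bs]
        cursor += bs

        xb = X[idx]
        zb, enc_cache = encoder.forward(xb)
        qb = soft_assign(zb, centroids, alpha)
        pb = P[idx]
        # dL/dz_i and dL/dmu_j for L = (1/B) sum KL(p_i || q_i)
        diff = zb[:, None, :] - centroids[None, :, :]
        d2 = (diff**2).sum(axis=2)
        coef = ((alpha + 1.0) / alpha) * (pb - qb) / (1.0 + d2 / alpha) / xb.shape[0]
        dz = (coef[:, :, None] * diff).sum(axis=1)
        dmu = -(coef[:, :, None] * diff).sum(axis=0)
        gW, gb, _ = encoder.backward(enc_cache, dz)
        encoder.sgd_step(gW, gb, lr, mom)
        v_mu = mom * v_mu - lr * dmu
        centroids = centroids + v_mu

        if it % update_interval == 0 or it == max_iter:
            Z = ae.encode(X)
            Q = soft_assign(Z, centroids, alpha)
            _check_rows(Q, "Q")
            P = target_distribution(Q)
            _check_rows(P, "P")
            labels = np.argmax(Q, axis=1)
            frac = float(np.mean(labels != prev_labels))
            loss = kl_loss(P, Q)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite KL loss at iteration {it}")
            trace.append(TrainState(it, loss, frac, max_iter=max_iter, tol=tol))
            prev_labels = labels
            if frac < tol:
                break

    model = DECModel(autoencoder=ae, centroids=centroids, alpha=alpha, k=k)
    labels = model.predict(X)
    used = np.unique(labels)
    result = ClusteringResult(
        labels=labels,
        k=k,
        algorithm="dec",
        seed=spec.seed,
        diagnostics={
            "kl_trace": [t.kl_loss for t in trace],
            "iterations": trace[-1].iteration,
            "n_clusters_used": int(used.size),
            "converged": trace[-1].label_change_fraction < tol,
        },
    )
    return model, result, trace


def run_dec_ensemble(
    fm,
    k: int,
    n_runs: int = 100,
    base_seed: int = 0,
    spec: AutoencoderSpec | None = None,
    **train_kwargs,
) -> list[tuple[DECModel, ClusteringResult]]:
    """Independent DEC trainings with seeds base_seed .. base_seed + n_runs - 1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = spec or AutoencoderSpec()
    out = []
    for r in range(n_runs):
        run_spec = replace(spec, seed=base_seed + r)
        try:
            model, result, _ = train_dec(fm, k, spec=run_spec, **train_kwargs)
        except Exception as exc:  # annotate with run index, then re-raise
            raise RuntimeError(f"DEC ensemble run {r} (seed {base_seed + r}) failed") from exc
        out.append((model, result))
    return out
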