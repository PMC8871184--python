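"""Linguistic Constrained EM (LCEM) for Gaussian mixture symbolization.

A diagonal-covariance Gaussian mixture is fitted by EM, but the mixing
weights are constrained toward a Zipf-Mandelbrot-Li target: at every M-step
the likelihood-driven weight update w_hat is blended with the ZML
probabilities matched to the clusters' descending-weight ranks,

    w_new = (1 - eta) * w_hat + eta * z_match,       eta in [0, 1],

so eta=0 recovers plain EM and eta=1 pins the sorted weights to the ZML law
exactly.  Convergence of the constrained weights is monitored by an
*entropic error* — the KL divergence between the descending-sorted weights
and the ZML target — and the stopping rule watches the entropy of the
weight vector, since the symbol probabilities are the quantity of interest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .zml import ZMLDistribution, zml_probabilities

__all__ = [
    "MixtureModel",
    "FitTrace",
    "entropic_error",
    "initialize_mixture",
    "e_step",
    "m_step_constrained",
    "fit_lcem",
]

_WEIGHT_FLOOR = 1e-12


@dataclass
class MixtureModel:
    """Diagonal-covariance Gaussian mixture with a ZML weight target."""

    means: np.ndarray  # (M, d)
    variances: np.ndarray  # (M, d), all > 0
    weights: np.ndarray  # (M,), sums to 1
    target: ZMLDistribution

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        M = self.n_clusters
        if self.variances.shape != self.means.shape:
            raise ValueError("means and variances must have matching shapes")
        if self.weights.shape != (M,) or self.target.alphabet_size != M:
            raise ValueError("weights and target must have one entry per cluster")
        if np.any(self.variances <= 0):
            raise ValueError("all variances must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights <= 0) or np.any(self.weights >= 1):
            if M > 1:
                raise ValueError("weights must lie in (0,1) and sum to 1 within 1e-9")

    @property
    def n_clusters(self) -> int:
        return self.means.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "weights": self.weights.tolist(),
                "target": json.loads(self.target.to_json()),
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "MixtureModel":
        d = json.loads(doc)
        target = ZMLDistribution.from_json(json.dumps(d["target"]))
        return cls(
            np.asarray(d["means"]), np.asarray(d["variances"]), np.asarray(d["weights"]), target
        )


@dataclass
class FitTrace:
    """Per-iteration diagnostics of an LCEM fit."""

    loglik: list[float] = field(default_factory=list)  # mean per-sample log-likelihood
    entropic_error: list[float] = field(default_factory=list)  # bits
    weights: list[np.ndarray] = field(default_factory=list)
    entropy: list[float] = field(default_factory=list)  # bits

    @property
    def n_iterations(self) -> int:
        return len(self.loglik)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "loglik": self.loglik,
                "entropic_error": self.entropic_error,
                "entropy": self.entropy,
            }
        )


def _weight_entropy(w: np.ndarray) -> float:
    w = w[w > 0]
    return float(-np.sum(w * np.log2(w)))


def entropic_error(weights, target: ZMLDistribution) -> float:
    """KL divergence D(sorted_desc(weights) || target) in bits.

    Zero iff the multiset of weights equals the ZML probabilities; sorting
    makes the error invariant to cluster labelling.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (target.alphabet_size,):
        raise ValueError("weights length must equal the target alphabet size")
    p = np.sort(w)[::-1]
    q = target.probs
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def _log_gauss_diag(data: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    # (n, M) log densities of diagonal Gaussians
    n, d = data.shape
    diff = data[:, None, :] - means[None, :, :]  # (n, M, d)
    return -0.5 * (
        np.sum(diff**2 / variances[None, :, :], axis=2)
        + np.sum(np.log(2 * np.pi * variances), axis=1)[None, :]
    )


def e_step(model: MixtureModel, data) -> np.ndarray:
    """Responsibilities: P(cluster k | sample i), computed in the log domain."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    log_r = _log_gauss_diag(X, model.means, model.variances) + np.log(model.weights)[None, :]
    log_r -= logsumexp(log_r, axis=1, keepdims=True)
    return np.exp(log_r)


def _mean_loglik(model: MixtureModel, data: np.ndarray) -> float:
    log_joint = _log_gauss_diag(data, model.means, model.variances) + np.log(model.weights)
    return float(np.mean(logsumexp(log_joint, axis=1)))


def _zml_match(w_hat: np.ndarray, target: ZMLDistribution) -> np.ndarray:
    """Assign each cluster the ZML probability of its descending-weight rank."""
    order = np.argsort(-w_hat, kind="stable")
    z = np.empty_like(w_hat)
    z[order] = target.probs
    return z


def m_step_constrained(
    model: MixtureModel, data, resp, eta: float, variance_floor: float | None = None
) -> MixtureModel:
    """Constrained M-step: standard mean/variance updates, blended weights.

    ``variance_floor`` defaults to 1e-6 of the total data variance.  Empty
    clusters (total responsibility below 1e-8 * n) are re-seeded at the
    sample with the lowest total density under the current model.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    X = np.atleast_2d(np.asarray(data, dtype=float))
    R = np.asarray(resp, dtype=float)
    n, d = X.shape
    M = model.n_clusters
    if R.shape != (n, M):
        raise ValueError("responsibility matrix shape must be (n_samples, n_clusters)")
    if variance_floor is None:
        variance_floor = 1e-6 * float(np.var(X))
    variance_floor = max(variance_floor, 1e-300)

    nk = R.sum(axis=0)
    empty = np.flatnonzero(nk < 1e-8 * n)
    means = model.means.copy()
    variances = model.variances.copy()
    live = np.setdiff1d(np.arange(M), empty)
    means[live] = (R[:, live].T @ X) / nk[live, None]
    for k in live:
        diff = X - means[k]
        variances[k] = np.maximum((R[:, k] @ diff**2) / nk[k], variance_floor)
    if empty.size:
        warnings.warn(f"re-seeding {empty.size} empty cluster(s)", RuntimeWarning)
        log_density = logsumexp(
            _log_gauss_diag(X, model.means, model.variances) + np.log(model.weights), axis=1
        )
        worst = np.argsort(log_density)
        for j, k in enumerate(empty):
            means[k] = X[worst[j % n]]
            variances[k] = np.maximum(np.var(X, axis=0), variance_floor)
            nk[k] = 1.0

    w_hat = nk / nk.sum()
    w_hat = np.maximum(w_hat, _WEIGHT_FLOOR)
    w_hat /= w_hat.sum()
    w_new = (1.0 - eta) * w_hat + eta * _zml_match(w_hat, model.target)
    w_new /= w_new.sum()
    return MixtureModel(means, variances, w_new, model.target)


def initialize_mixture(data, n_clusters: int, seed: int) -> MixtureModel:
    """Seeded initialization: k-means++ means, data variances, uniform weights."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    M = int(n_clusters)
    centers, _ = kmeans_plusplus(X, n_clusters=M, random_state=seed)
    variances = np.tile(np.maximum(np.var(X, axis=0), 1e-12), (M, 1))
    weights = np.full(M, 1.0 / M)
    return MixtureModel(centers, variances, weights, zml_probabilities(M))


def fit_lcem(
    data,
    n_clusters: int,
    eta: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
) -> tuple[MixtureModel, FitTrace]:
    """Fit an LCEM mixture: alternate E-step and constrained M-step.

    Iteration stops when the absolute change of the weight-vector entropy
    drops below ``tol`` (or ``max_iter`` is reached); the trace records the
    mean per-sample log-likelihood, entropic error, weights and weight
    entropy at every iteration.  Fully reproducible for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < n_clusters:
        raise ValueError(f"need at least {n_clusters} samples, got {X.shape[0]}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    model = initialize_mixture(X, n_clusters, seed)
    trace = FitTrace()
    prev_entropy = _weight_entropy(model.weights)
    for _ in range(max_iter):
        resp = e_step(model, X)
        model = m_step_constrained(model, X, resp, eta)
        trace.loglik.append(_mean_loglik(model, X))
        trace.entropic_error.append(entropic_error(model.weights, model.target))
        trace.weights.append(model.weights.copy())
        h = _weight_entropy(model.weights)
        trace.entropy.append(h)
        if abs(h - prev_entropy) < tol:
            break
        prev_entropy = h
    return model, trace
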