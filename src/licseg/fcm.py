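"""Fuzzy c-means (FCM) clustering on per-pixel feature vectors.

FCM minimises the fuzzified within-cluster scatter

    J(U, V) = sum_i sum_k  u_ik**m * ||x_k - v_i||**2,

subject to sum_i u_ik = 1, by alternating the standard update rules

    v_i  = sum_k u_ik**m x_k / sum_k u_ik**m
    u_ik = 1 / sum_j (d_ik / d_jk)**(2/(m-1))

with Euclidean distances d_ik = ||x_k - v_i||.  The fuzziness exponent m > 1
controls how soft the partition is; m = 2 is used throughout the pipeline.
A point coinciding with a centroid (d = 0) receives crisp membership 1 for
that cluster.  Returned clusters are sorted ascending by the first centroid
component so cluster indices are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InsufficientDataError, ValidationError

INIT_METHODS = ("quantile-spread", "random-sample")


@dataclass
class FCMConfig:
    """Parameters of an FCM run.

    ``quantile-spread`` initialisation places centroids at evenly spaced data
    quantiles (deterministic, seed-independent); ``random-sample`` draws
    ``n_clusters`` distinct data points using ``seed``.
    """

    n_clusters: int
    fuzziness: float = 2.0
    tolerance: float = 1e-5
    max_iterations: int = 300
    seed: int = 0
    init_method: str = "quantile-spread"

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if not self.fuzziness > 1:
            raise ValidationError("fuzziness must be > 1")
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.init_method not in INIT_METHODS:
            raise ValidationError(f"init_method must be one of {INIT_METHODS}")


@dataclass
class FCMResult:
    centroids: np.ndarray  # (c, d)
    membership: np.ndarray  # (N, c), rows sum to 1
    objective_history: np.ndarray
    n_iterations: int
    converged: bool


def _init_centroids(data: np.ndarray, cfg: FCMConfig) -> np.ndarray:
    n, d = data.shape
    c = cfg.n_clusters
    if cfg.init_method == "random-sample":
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(n, size=c, replace=False)
        centroids = data[idx].astype(float).copy()
    else:
        q = (np.arange(c) + 0.5) / c
        centroids = np.quantile(data, q, axis=0).astype(float)
    # collapse-proof: identical initial centroids would never separate
    for j in range(d):
        col = centroids[:, j]
        if np.unique(col).size < c:
            span = float(data[:, j].max() - data[:, j].min())
            centroids[:, j] = col + np.linspace(0.0, 1.0, c) * max(span, 1.0) * 1e-6
    return centroids


def _memberships(data: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    # d2: (N, c) squared Euclidean distances
    diff = data[:, None, :] - centroids[None, :, :]
    d2 = np.einsum("ncd,ncd->nc", diff, diff)
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = 0.0
        # crisp assignment to the (first) coinciding centroid
        first = zero[any_zero].argmax(axis=1)
        u[np.flatnonzero(any_zero), first] = 1.0
    return u


def _objective(data, centroids, u, m) -> float:
    diff = data[:, None, :] - centroids[None, :, :]
    d2 = np.einsum("ncd,ncd->nc", diff, diff)
    return float(np.sum((u**m) * d2))


def fcm_cluster(data: np.ndarray, config: FCMConfig) -> FCMResult:
    """Cluster ``data`` (N x d, or a flat vector treated as N x 1).

    Iterates the alternating update rules until the largest centroid
    displacement falls below ``config.tolerance`` or ``max_iterations`` is
    reached.  Deterministic for a fixed config (and seed, for random init).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValidationError("data must be a vector or an N x d matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("data must be finite")
    n, d = x.shape
    c = config.n_clusters
    if n < c:
        raise InsufficientDataError(f"need at least {c} samples, got {n}")
    m = config.fuzziness

    if c == 1:
        centroid = x.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        return FCMResult(
            centroids=centroid,
            membership=u,
            objective_history=np.array([_objective(x, centroid, u, m)]),
            n_iterations=0,
            converged=True,
        )

    v = _init_centroids(x, config)
    history: list[float] = []
    converged = False
    it = 0
    u = _memberships(x, v, m)
    for it in range(1, config.max_iterations + 1):
        um = u**m
        v_new = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = float(np.abs(v_new - v).max())
        v = v_new
        u = _memberships(x, v, m)
        history.append(_objective(x, v, u, m))
        if shift < config.tolerance:
            converged = True
            break

    order = np.argsort(v[:, 0], kind="stable")
    return FCMResult(
        centroids=v[order],
        membership=u[:, order],
        objective_history=np.asarray(history),
        n_iterations=it,
        converged=converged,
    )


def harden_by_threshold(result: FCMResult, cluster_index: int, mt: float) -> np.ndarray:
    """Boolean vector: sample k is kept iff u[k, cluster_index] >= mt.

    ``mt`` is the membership threshold (MT); ties at exactly ``mt`` are kept.
    """
    if not (0.0 < mt < 1.0):
        raise ValidationError("membership threshold must be in (0, 1)")
    c = result.membership.shape[1]
    if not (0 <= cluster_index < c):
        raise ValidationError(f"cluster_index {cluster_index} out of range [0, {c})")
    return result.membership[:, cluster_index] >= mt


def select_cluster_by_max_centroid(result: FCMResult, feature_index: int = 0) -> int:
    """Index of the cluster with the largest centroid component.

    Ties break toward the lowest index.  With intensity (or LIC) features this
    picks the brightest / highest-burden cluster.
    """
    d = result.centroids.shape[1]
    if not (0 <= feature_index < d):
        raise ValidationError(f"feature_index {feature_index} out of range [0, {d})")
    return int(np.argmax(result.centroids[:, feature_index]))
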