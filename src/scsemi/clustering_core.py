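"""Latent-space deep clustering machinery.

Cluster centers live in the autoencoder's latent space. Soft assignments Q
use a Student's-t kernel with one degree of freedom; the target distribution
P is the squared-frequency-normalized sharpening of Q; the deep-clustering
loss is a Gaussian-kernel weighted soft K-means term plus KL(P || Q). The
Gaussian kernel bandwidth ("temperature") is annealed geometrically during
training so the soft weights sharpen over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2

from . import _tape as T

Q_CLIP = 1e-12


@dataclass
class ClusterState:
    centers: np.ndarray
    Q: np.ndarray | None = None
    P: np.ndarray | None = None
    omega: np.ndarray | None = None
    hard_labels: np.ndarray | None = None
    temperature: float = 1.0
    decay: float = 0.95
    temperature_floor: float = 0.1

    def anneal(self) -> None:
        self.temperature = max(self.temperature * self.decay,
                               self.temperature_floor)


def _sq_dists(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def init_centers(z: np.ndarray, K: int, seed: int = 0,
                 labeled: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> np.ndarray:
    """Seeded K-means initialization of the K x d center matrix.

    When ``labeled = (indices, labels)`` is given, each labeled class's
    latent centroid replaces its nearest unsupervised center, one-to-one and
    greedy by distance, anchoring cluster indices to classes.
    """
    z = np.asarray(z, dtype=np.float64)
    if K > z.shape[0]:
        raise ValueError(f"K={K} exceeds the number of cells ({z.shape[0]})")
    centers, _ = kmeans2(z, K, iter=50, minit="++", seed=seed)
    if labeled is not None and len(labeled[0]) > 0:
        idx, labels = np.asarray(labeled[0]), np.asarray(labeled[1])
        classes = np.unique(labels)
        centroids = np.stack([z[idx[labels == c]].mean(axis=0) for c in classes])
        d = _sq_dists(centroids, centers)          # classes x centers
        free_classes = set(range(len(classes)))
        free_centers = set(range(K))
        while free_classes:
            sub = d[np.ix_(sorted(free_classes), sorted(free_centers))]
            r, c = np.unravel_index(np.argmin(sub), sub.shape)
            ci = sorted(free_classes)[r]
            cj = sorted(free_centers)[c]
            centers[cj] = centroids[ci]
            free_classes.remove(ci)
            free_centers.remove(cj)
    return centers


def soft_kmeans_loss(z: np.ndarray, centers: np.ndarray,
                     temperature: float) -> tuple[float, np.ndarray]:
    """Weighted soft K-means objective and its Gaussian-kernel weights.

    omega_ij = exp(-||z_i - c_j||^2 / temperature), row-normalized; the loss
    is the omega-weighted mean squared distance. omega is a constant within
    an optimization step (no gradient flows through it).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    d2 = _sq_dists(np.asarray(z, float), np.asarray(centers, float))
    logw = -d2 / temperature
    logw -= logw.max(axis=1, keepdims=True)
    omega = np.exp(logw)
    omega /= omega.sum(axis=1, keepdims=True)
    loss = float((omega * d2).sum() / z.shape[0])
    return loss, omega


def soft_assign(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student's-t (df=1) soft assignment Q: q_ij ∝ (1 + ||z_i - c_j||^2)^-1."""
    d2 = _sq_dists(np.asarray(z, float), np.asarray(centers, float))
    q = 1.0 / (1.0 + d2)
    return q / q.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target P: p_ij ∝ q_ij^2 / f_j with cluster frequency f_j."""
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        empty = np.flatnonzero(f <= 0)
        raise ValueError(f"empty cluster(s) {empty.tolist()} in target distribution")
    w = Q ** 2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean per-cell KL(P || Q); P is a constant target between refreshes."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    Pc = np.clip(P, Q_CLIP, None)
    Qc = np.clip(Q, Q_CLIP, None)
    return float((P * (np.log(Pc) - np.log(Qc))).sum() / P.shape[0])


def deep_cluster_loss(z: np.ndarray, centers: np.ndarray,
                      temperature: float, P: np.ndarray) -> float:
    """Soft K-means term plus KL term with Q recomputed from (z, centers)."""
    sk, _ = soft_kmeans_loss(z, centers, temperature)
    return sk + kl_loss(P, soft_assign(z, centers))


# ---------------------------------------------------------------------------
# tape versions used inside the training step
# ---------------------------------------------------------------------------

def _transpose(a: T.Tensor) -> T.Tensor:
    return T._make(a.value.T, (a,), (lambda g: g.T,))


def sq_dists_t(z: T.Tensor, centers: T.Tensor) -> T.Tensor:
    z2 = T.tsum(T.power(z, 2.0), axis=1, keepdims=True)        # n x 1
    c2 = T.tsum(T.power(centers, 2.0), axis=1, keepdims=True)  # K x 1
    cross = z @ _transpose(centers)
    return z2 + _transpose(c2) - 2.0 * cross


def soft_assign_t(z: T.Tensor, centers: T.Tensor) -> T.Tensor:
    d2 = sq_dists_t(z, centers)
    q = T.power(1.0 + d2, -1.0)
    return q / T.tsum(q, axis=1, keepdims=True)


def soft_kmeans_loss_t(z: T.Tensor, centers: T.Tensor,
                       temperature: float) -> T.Tensor:
    _, omega = soft_kmeans_loss(z.value, centers.value, temperature)
    d2 = sq_dists_t(z, centers)
    return T.tsum(T.Tensor(omega) * d2) / float(z.shape[0])


def kl_loss_t(P: np.ndarray, Q: T.Tensor) -> T.Tensor:
    Pc = np.clip(P, Q_CLIP, None)
    logQ = T.log(T.clip(Q, Q_CLIP, 2.0))
    return T.tsum(T.Tensor(P) * (T.Tensor(np.log(Pc)) - logQ)) / float(P.shape[0])
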