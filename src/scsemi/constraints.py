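"""Semisupervised constraints from a partially labeled cell set.

A stratified fraction r of cells is treated as labeled. From those cells the
model draws (anchor, positive, negative) triplets, a must-link/cannot-link
pair matrix Y, and inverse-frequency class weights. The three losses act on
the soft-assignment rows of Q:

* triplet hinge on the dot-product similarity s(a, b) = sum_j q_aj q_bj,
* binary cross-entropy between Y and the cosine similarity of Q rows,
* class-weighted cross-entropy after aligning clusters to classes with the
  Hungarian method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import _tape as T

_EPS = 1e-12


@dataclass
class ConstraintSet:
    """Everything the semisupervised losses need, fixed once per run."""

    labeled_idx: np.ndarray                 # indices into the cell axis
    labels: np.ndarray                      # class index per labeled cell
    triplets: np.ndarray                    # n_triplets x 3 (anchor, pos, neg)
    Y: np.ndarray                           # labeled x labeled binary matrix
    class_weights: np.ndarray               # per-class, frequency-weighted mean 1
    margin: float = 0.1
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_labeled(self) -> int:
        return len(self.labeled_idx)

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)


def empty_constraints() -> ConstraintSet:
    """The unsupervised arm: no labeled cells, no triplets."""
    return ConstraintSet(
        labeled_idx=np.array([], dtype=int), labels=np.array([], dtype=int),
        triplets=np.empty((0, 3), dtype=int), Y=np.empty((0, 0)),
        class_weights=np.array([]))


@dataclass
class ClusterClassMap:
    """Injective class -> cluster assignment (Hungarian, max agreement)."""

    mapping: dict[int, int]

    def cluster_of(self, cls: int) -> int:
        if cls not in self.mapping:
            raise KeyError(f"class {cls} has no mapped cluster")
        return self.mapping[cls]


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, enc = np.unique(np.asarray(labels), return_inverse=True)
    return classes, enc


def make_labeled_mask(labels: np.ndarray, r: float, seed: int = 0) -> np.ndarray:
    """Stratified labeled-cell sample: ceil(r * n_c) cells per class c."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"labeled fraction r={r} outside [0, 1]")
    labels = np.asarray(labels)
    if r == 0.0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    picked = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        k = min(len(members), int(np.ceil(r * len(members))))
        picked.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def sample_triplets(labeled_idx: np.ndarray, labels: np.ndarray,
                    n_triplets: int = 10000, seed: int = 0) -> np.ndarray:
    """Uniformly sampled (anchor, positive, negative) cell-index triples.

    ``labels`` are per-cell over all cells; anchors are drawn from labeled
    cells whose class has at least two labeled members, positives from the
    anchor's class, negatives from any other labeled class.
    """
    labeled_idx = np.asarray(labeled_idx)
    labels = np.asarray(labels)
    lab = labels[labeled_idx]
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValueError("triplet sampling needs at least 2 labeled classes")
    counts = {c: int((lab == c).sum()) for c in classes}
    anchor_pool = labeled_idx[np.isin(lab, [c for c in classes if counts[c] >= 2])]
    if len(anchor_pool) == 0:
        raise ValueError("no labeled class has >= 2 members")
    rng = np.random.default_rng(seed)
    by_class = {c: labeled_idx[lab == c] for c in classes}
    anchors = rng.choice(anchor_pool, size=n_triplets)
    pos = np.empty(n_triplets, dtype=int)
    neg = np.empty(n_triplets, dtype=int)
    for t, a in enumerate(anchors):
        ca = labels[a]
        same = by_class[ca]
        p = a
        while p == a:
            p = rng.choice(same)
        others = classes[classes != ca]
        neg_class = rng.choice(others)
        pos[t] = p
        neg[t] = rng.choice(by_class[neg_class])
    return np.column_stack([anchors, pos, neg])


def triplet_loss(Q: np.ndarray, triplets: np.ndarray, margin: float = 0.1,
                 form: str = "corrected") -> float:
    """Mean triplet hinge over sampled triples.

    With the default ``corrected`` form the hinge is
    max(s(A,N) - s(A,P) + margin, 0), pushing the anchor's assignment vector
    toward the positive's and away from the negative's. ``literal`` swaps the
    two similarity terms.
    """
    if len(triplets) == 0:
        warnings.warn("empty triplet list; triplet loss is 0", stacklevel=2)
        return 0.0
    Q = np.asarray(Q, dtype=np.float64)
    a, p, n = triplets[:, 0], triplets[:, 1], triplets[:, 2]
    s_ap = (Q[a] * Q[p]).sum(axis=1)
    s_an = (Q[a] * Q[n]).sum(axis=1)
    if form == "corrected":
        h = np.maximum(s_an - s_ap + margin, 0.0)
    elif form == "literal":
        h = np.maximum(s_ap - s_an + margin, 0.0)
    else:
        raise ValueError(f"unknown triplet form {form!r}")
    return float(h.mean())


def pairwise_similarity(Q_labeled: np.ndarray) -> np.ndarray:
    """Cosine similarity between per-cell assignment rows; diagonal is 1."""
    Q = np.asarray(Q_labeled, dtype=np.float64)
    norms = np.linalg.norm(Q, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero assignment row in pairwise similarity")
    S = (Q @ Q.T) / np.outer(norms, norms)
    np.fill_diagonal(S, 1.0)
    return S


def pairwise_loss(S: np.ndarray, Y: np.ndarray) -> float:
    """Mean off-diagonal binary cross-entropy between Y and S."""
    S = np.asarray(S, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if S.shape != Y.shape or S.shape[0] != S.shape[1]:
        raise ValueError(f"shape mismatch: S {S.shape} vs Y {Y.shape}")
    n = S.shape[0]
    if n < 2:
        return 0.0
    Sc = np.clip(S, _EPS, 1.0 - _EPS)
    bce = -(Y * np.log(Sc) + (1.0 - Y) * np.log(1.0 - Sc))
    off = ~np.eye(n, dtype=bool)
    return float(bce[off].mean())


def label_matrix(labels_labeled: np.ndarray) -> np.ndarray:
    """Must-link/cannot-link matrix: Y_ij = 1 iff labels match."""
    lab = np.asarray(labels_labeled)
    return (lab[:, None] == lab[None, :]).astype(np.float64)


def align_clusters(Q_labeled: np.ndarray, labels_labeled: np.ndarray
                   ) -> ClusterClassMap:
    """Hungarian alignment of classes to clusters on the labeled contingency."""
    Q = np.asarray(Q_labeled, dtype=np.float64)
    classes, enc = _encode_labels(labels_labeled)
    hard = Q.argmax(axis=1)
    K = Q.shape[1]
    cont = np.zeros((len(classes), K))
    np.add.at(cont, (enc, hard), 1.0)
    rows, cols = linear_sum_assignment(-cont)
    return ClusterClassMap({classes[r]: int(c) for r, c in zip(rows, cols)})


def class_weights(labels_labeled: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights w_j = n_r / (K_t * n_j), ordered by class."""
    labels = np.asarray(labels_labeled)
    if labels.size == 0:
        raise ValueError("no labeled cells")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty class")
    return labels.size / (len(classes) * counts.astype(np.float64))


def weighted_ce_loss(Q_labeled: np.ndarray, labels_labeled: np.ndarray,
                     mapping: ClusterClassMap, weights: np.ndarray) -> float:
    """Class-weighted cross-entropy of labeled cells against their mapped
    cluster probabilities (renormalized over the mapped clusters)."""
    Q = np.asarray(Q_labeled, dtype=np.float64)
    classes, enc = _encode_labels(labels_labeled)
    cols = np.array([mapping.cluster_of(c) for c in classes])
    p = Q[:, cols]
    p = p / np.clip(p.sum(axis=1, keepdims=True), _EPS, None)
    p_true = np.clip(p[np.arange(len(enc)), enc], _EPS, None)
    w = np.asarray(weights)[enc]
    return float(-(w * np.log(p_true)).mean())


def build_constraints(labels: np.ndarray, r: float = 0.10,
                      n_triplets: int = 10000, margin: float = 0.1,
                      seed: int = 0) -> ConstraintSet:
    """Assemble the full ConstraintSet from all-cell labels."""
    labels = np.asarray(labels)
    idx = make_labeled_mask(labels, r, seed)
    if len(idx) == 0:
        return empty_constraints()
    lab = labels[idx]
    classes, _ = _encode_labels(lab)
    triplets = (sample_triplets(idx, labels, n_triplets, seed)
                if len(classes) >= 2 and n_triplets > 0
                else np.empty((0, 3), dtype=int))
    return ConstraintSet(
        labeled_idx=idx, labels=lab, triplets=triplets,
        Y=label_matrix(lab), class_weights=class_weights(lab),
        margin=margin, classes=classes)


# ---------------------------------------------------------------------------
# tape versions used inside the training step
# ---------------------------------------------------------------------------

def triplet_loss_t(Q_a: T.Tensor, Q_p: T.Tensor, Q_n: T.Tensor,
                   margin: float, form: str = "corrected") -> T.Tensor:
    s_ap = T.tsum(Q_a * Q_p, axis=1)
    s_an = T.tsum(Q_a * Q_n, axis=1)
    diff = (s_an - s_ap) if form == "corrected" else (s_ap - s_an)
    return T.tmean(T.maximum(diff + margin, T.Tensor(np.zeros(s_ap.shape))))


def pairwise_loss_t(Q_lab: T.Tensor, Y: np.ndarray) -> T.Tensor:
    n = Y.shape[0]
    norms = T.sqrt(T.tsum(T.power(Q_lab, 2.0), axis=1, keepdims=True) + _EPS)
    Qn = Q_lab / norms
    S = T.clip(Qn @ T._make(Qn.value.T, (Qn,), (lambda g: g.T,)),
               _EPS, 1.0 - _EPS)
    bce = -(T.Tensor(Y) * T.log(S) + T.Tensor(1.0 - Y) * T.log(1.0 - S))
    off = (~np.eye(n, dtype=bool)).astype(np.float64)
    return T.tsum(T.Tensor(off) * bce) / float(off.sum())


def weighted_ce_loss_t(Q_lab: T.Tensor, enc_labels: np.ndarray,
                       cols: np.ndarray, weights_per_cell: np.ndarray
                       ) -> T.Tensor:
    p = T.take_cols(Q_lab, cols)
    p = p / T.clip(T.tsum(p, axis=1, keepdims=True), _EPS, 1e9)
    onehot = np.zeros((len(enc_labels), len(cols)))
    onehot[np.arange(len(enc_labels)), enc_labels] = 1.0
    p_true = T.tsum(T.Tensor(onehot) * p, axis=1)
    logp = T.log(T.clip(p_true, _EPS, 1e9))
    return -T.tmean(T.Tensor(weights_per_cell) * logp)
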