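"""External clustering agreement metrics: NMI, ARI, AMI, and Hungarian ACC."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm


def _check(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError(f"partition lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty partitions")
    return a, b


def nmi(a, b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information (entropy normalization selectable,
    arithmetic-mean by default)."""
    a, b = _check(a, b)
    return float(skm.normalized_mutual_info_score(a, b,
                                                  average_method=average_method))


def ari(a, b) -> float:
    """Adjusted Rand index over the pair-counting contingency."""
    a, b = _check(a, b)
    return float(skm.adjusted_rand_score(a, b))


def ami(a, b, average_method: str = "arithmetic") -> float:
    """Adjusted mutual information under the hypergeometric null."""
    a, b = _check(a, b)
    return float(skm.adjusted_mutual_info_score(a, b,
                                                average_method=average_method))


def acc(truth, pred) -> float:
    """Clustering accuracy: best one-to-one cluster-to-class matching
    (Hungarian method on the contingency table)."""
    truth, pred = _check(truth, pred)
    t_classes, t = np.unique(truth, return_inverse=True)
    p_classes, p = np.unique(pred, return_inverse=True)
    cont = np.zeros((len(t_classes), len(p_classes)))
    np.add.at(cont, (t, p), 1.0)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(truth))


def all_metrics(truth, pred) -> dict[str, float]:
    return {"nmi": nmi(truth, pred), "ari": ari(truth, pred),
            "ami": ami(truth, pred), "acc": acc(truth, pred)}
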