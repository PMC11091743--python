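"""Splat-style simulation of group-structured scRNA-seq counts.

A simplified reimplementation of the splat generative model (single batch,
"groups" mode only, no trajectories): gamma-distributed gene base means,
log-normal per-group differential-expression factors on a random subset of
genes, log-normal library sizes, gamma-Poisson (negative binomial) counts
with a common biological coefficient of variation, and a logistic
mean-dependent dropout curve. Exact numerical agreement with the R package
is a non-goal; group structure and count marginals are what downstream
clustering needs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import CountMatrix


@dataclass
class SimParams:
    """Generative parameters; defaults follow splat's published defaults."""

    n_cells: int = 2000
    n_genes: int = 10000
    group_prob: tuple = (0.05, 0.1, 0.2, 0.65)
    mean_shape: float = 0.6      # gamma shape of gene base means
    mean_rate: float = 0.3       # gamma rate of gene base means
    lib_loc: float = 11.0        # log-normal location of library sizes
    lib_scale: float = 0.2       # log-normal scale of library sizes
    de_prob: float = 0.1         # fraction of genes DE in each group
    de_fac_loc: float = 0.1      # log-normal location of DE factors
    de_fac_scale: float = 0.4    # log-normal scale of DE factors
    bcv: float = 0.2             # biological coefficient of variation
    dropout_mid: float = 1.0     # logistic dropout midpoint
    dropout_shape: float = 1.0   # logistic dropout steepness
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.group_prob, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"group_prob must be nonnegative and sum to 1 (got sum={p.sum()!r})"
            )
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_prob)


_PRESETS = {
    "splat1": dict(n_genes=10000, n_cells=2000,
                   group_prob=(0.05, 0.1, 0.2, 0.65)),
    "splat2": dict(n_genes=10000, n_cells=5000,
                   group_prob=(0.05, 0.1, 0.2, 0.65)),
    "splat3": dict(n_genes=10000, n_cells=10000,
                   group_prob=(0.05, 0.1, 0.2, 0.65)),
    "splat4": dict(n_genes=10000, n_cells=2000,
                   group_prob=(0.02, 0.03, 0.2, 0.65, 0.03, 0.07)),
    "splat5": dict(n_genes=10000, n_cells=2000,
                   group_prob=(0.02, 0.02, 0.03, 0.05, 0.08,
                               0.1, 0.1, 0.15, 0.15, 0.3)),
}


def preset(name: str, **overrides) -> SimParams:
    """Return one of the named simulation configurations (splat1..splat5)."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    return replace(SimParams(**_PRESETS[name]), **overrides)


def simulate(params: SimParams) -> tuple[CountMatrix, np.ndarray]:
    """Draw a cells x genes count matrix and true group labels.

    Fully reproducible from ``params.seed``. Group membership is sampled from
    ``group_prob`` (not deterministically allocated), so realized group sizes
    fluctuate around the expectation.
    """
    rng = np.random.default_rng(params.seed)
    n, g, k = params.n_cells, params.n_genes, params.n_groups

    base_means = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, size=g)

    # per-group multiplicative DE factors; non-DE genes keep factor 1
    factors = np.ones((k, g))
    for grp in range(k):
        de_mask = rng.random(g) < params.de_prob
        raw = np.exp(rng.normal(params.de_fac_loc, params.de_fac_scale,
                                size=de_mask.sum()))
        down = rng.random(de_mask.sum()) < 0.5
        raw[down] = 1.0 / raw[down]
        factors[grp, de_mask] = raw

    group_means = base_means[None, :] * factors          # k x g
    profiles = group_means / group_means.sum(axis=1, keepdims=True)

    groups = rng.choice(k, size=n, p=np.asarray(params.group_prob, dtype=float))
    libs = rng.lognormal(params.lib_loc, params.lib_scale, size=n)

    mean = libs[:, None] * profiles[groups]              # n x g expected counts
    if params.bcv > 0:
        shape = 1.0 / params.bcv ** 2
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    if params.dropout_shape > 0:
        logit = (params.dropout_mid - np.log(mean + 1.0)) * params.dropout_shape
        p_drop = 1.0 / (1.0 + np.exp(-logit))
        counts[rng.random((n, g)) < p_drop] = 0

    cm = CountMatrix(
        counts,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{j}" for j in range(g)],
        labels=groups.copy(),
    )
    return cm, groups
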