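# scsemi

Semisupervised deep clustering of single-cell RNA-seq counts.

Clustering is the first step of most scRNA-seq analyses, and it is hard
for well-known reasons: the data are high-dimensional, sparse, and full of
"false" zeros from dropout events. At the same time, partial labels are
often available — a sorted subpopulation, a marker-annotated subset, a
previous atlas — and purely unsupervised methods ignore them. `scsemi`
uses a small labeled fraction of cells (10% by default) to guide deep
embedded clustering of the full dataset.

## Model

Counts are modeled per entry with a zero-inflated negative binomial,

    P(x) = π δ₀(x) + (1 − π) NB(x | μ, θ),

whose parameters (dropout probability π, mean μ, dispersion θ) are emitted
by the three decoder heads of a denoising autoencoder
(256-128-32-128-256, ReLU). Clustering happens in the 32-dimensional
latent space: soft assignments `q_ij ∝ (1 + ‖z_i − φ_j‖²)⁻¹` (Student's t,
df 1) are pulled toward a sharpened target distribution via KL divergence,
together with a Gaussian-kernel weighted soft K-means term. Labeled cells
contribute three extra losses: a triplet hinge (anchor/positive/negative
cells, margin α = 0.1), a must-link/cannot-link binary cross-entropy on
the cosine similarity of assignment vectors, and a class-weighted
cross-entropy that protects rare cell types. The total objective is

    L = L_ZINB + γ₁ L_DC + γ₂ L_triplet + γ₃ L_pairwise + γ₄ L_WCE,

optimized with AdaDelta (lr 1.0, rho 0.9), 300 pretraining epochs on
L_ZINB, then joint training until cluster assignments stabilize. See
`docs/methods.md` for the full account. Everything runs on numpy (the
network, reverse-mode autodiff and optimizer are implemented in
`scsemi/_tape.py`), in float64, bit-reproducibly from a seed.

A splat-style simulator (`scsemi.splat_sim`) generates group-structured
count matrices — gamma gene means, per-group DE factors, log-normal
library sizes, gamma-Poisson counts, logistic dropout — with presets
(`splat1` .. `splat5`) spanning 2000–10 000 cells and 4–10 imbalanced
groups at 10 000 genes.

## Worked example

```python
import numpy as np
from scsemi import (SimParams, simulate, preprocess, run_pipeline,
                    TrainConfig, all_metrics)

params = SimParams(n_cells=400, n_genes=300,
                   group_prob=(0.05, 0.1, 0.2, 0.65),
                   de_fac_loc=1.0, seed=1)        # 4 imbalanced groups
cm, groups = simulate(params)
data = preprocess(cm)

cfg = TrainConfig(pretrain_epochs=300, max_joint_epochs=100, seed=0)
_, res, _ = run_pipeline(data, K=4, labels=groups, r=0.10,
                         n_triplets=10000, cfg=cfg)
print({k: round(v, 3) for k, v in all_metrics(groups, res.hard_labels).items()})
```

prints (about 30 s on one CPU core):

    {'nmi': 0.94, 'ari': 0.974, 'ami': 0.939, 'acc': 0.943}

i.e. with 10% of cells labeled the four groups — including one holding
only ~5% of cells — are recovered almost perfectly. Passing `labels=None,
r=0.0` gives the unsupervised arm, which on the same data reaches NMI
≈ 0.87: the semisupervised constraints close most of the remaining gap.
`res.z` holds the latent embedding, `res.Q` the soft assignments, and
`res.loss_history` the per-epoch loss components.

The same pipeline is available from the shell:

    scsemi simulate --preset splat1 --seed 0 --out sim
    scsemi fit --counts sim.counts.csv --labels sim.truth.csv \
               --k 4 --labeled-fraction 0.1 --out fit
    scsemi evaluate --truth sim.truth.csv --pred fit.labels.csv

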