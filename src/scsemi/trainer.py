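"""Training orchestration: ZINB pretraining and joint constrained clustering.

The total objective is

    L = L_ZINB + g1 * L_DC + g2 * L_triplet + g3 * L_pairwise + g4 * L_WCE

minimized with AdaDelta (learning rate 1.0, rho 0.9). The autoencoder is
first pretrained on L_ZINB alone with denoising corruption; joint training
then optimizes encoder, decoder and free cluster centers together, refreshing
the target distribution P and the cluster-to-class alignment once per epoch,
and stops when the fraction of cells whose hard label changed falls below
``stop_tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _tape as T
from . import clustering_core as cc
from . import constraints as cons
from .data_io import PreprocessedData
from .zinb_ae import AEConfig, ZINBAutoencoder, zinb_nll_t

logger = logging.getLogger("scsemi")


@dataclass
class TrainConfig:
    gamma1: float = 1.0
    gamma2: float = 1.0
    gamma3: float = 1.0
    gamma4: float = 1.0
    pretrain_epochs: int = 300
    max_joint_epochs: int = 300
    batch_size: int = 256
    lr: float = 1.0              # AdaDelta learning rate
    rho: float = 0.9             # AdaDelta decay
    stop_tol: float = 0.001     # stop when < this fraction of labels change
    seed: int = 0
    temperature0: float = 1.0    # Gaussian-kernel bandwidth, annealed
    temp_decay: float = 0.95
    temp_floor: float = 0.1
    triplet_form: str = "corrected"

    def __post_init__(self):
        if min(self.gamma1, self.gamma2, self.gamma3, self.gamma4) < 0:
            raise ValueError("loss coefficients must be >= 0")
        if self.pretrain_epochs < 1 or self.max_joint_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if not 0.0 < self.stop_tol <= 1.0:
            raise ValueError("stop_tol must be in (0, 1]")


@dataclass
class FitResult:
    hard_labels: np.ndarray
    Q: np.ndarray
    z: np.ndarray
    loss_history: list[dict] = field(default_factory=list)
    epochs_run: int = 0


def _batches(n: int, batch_size: int, perm: np.ndarray):
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _encode_eval(model: ZINBAutoencoder, x: np.ndarray,
                 chunk: int = 2048) -> np.ndarray:
    outs = [model.encode(x[i:i + chunk]).z for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def pretrain(model: ZINBAutoencoder, data: PreprocessedData,
             cfg: TrainConfig) -> list[float]:
    """Minimize the ZINB NLL alone with denoising corruption active.

    Returns the per-epoch mean batch loss history; the model is updated
    in place.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = T.AdaDelta(list(model.params.values()), lr=cfg.lr, rho=cfg.rho)
    n = data.x_input.shape[0]
    history = []
    for epoch in range(1, cfg.pretrain_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for b, bidx in enumerate(_batches(n, cfg.batch_size, perm)):
            xb = data.x_input[bidx]
            if model.cfg.noise_sd > 0:
                xb = xb + rng.normal(0.0, model.cfg.noise_sd, xb.shape)
            z = model.encode_t(T.Tensor(xb))
            logit_pi, mu, theta = model.decode_t(z, data.size_factors[bidx])
            loss = zinb_nll_t(data.x_raw[bidx], logit_pi, mu, theta)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"non-finite ZINB loss in pretraining epoch {epoch}, batch {b}"
                )
            opt.zero_grad()
            T.backward(loss)
            opt.step()
            losses.append(float(loss.value))
        history.append(float(np.mean(losses)))
        logger.debug("pretrain epoch %d: zinb=%.5f", epoch, history[-1])
    return history


def fit(model: ZINBAutoencoder, data: PreprocessedData,
        constraints: cons.ConstraintSet | None, K: int,
        cfg: TrainConfig) -> FitResult:
    """Joint training of the full objective from a pretrained model."""
    if K < 2:
        raise ValueError("K must be >= 2")
    cs = constraints if constraints is not None else cons.empty_constraints()
    rng = np.random.default_rng(cfg.seed)
    n = data.x_input.shape[0]

    z_all = _encode_eval(model, data.x_input)
    anchor = (cs.labeled_idx, cs.labels) if cs.n_labeled > 0 else None
    centers = T.Tensor(
        cc.init_centers(z_all, K, seed=cfg.seed, labeled=anchor),
        requires_grad=True)
    opt = T.AdaDelta(list(model.params.values()) + [centers],
                     lr=cfg.lr, rho=cfg.rho)

    use_trip = cfg.gamma2 > 0 and len(cs.triplets) > 0
    use_pw = cfg.gamma3 > 0 and cs.n_labeled > 1
    use_wce = cfg.gamma4 > 0 and cs.n_labeled > 0
    if cs.n_labeled > 0:
        classes, enc_labels = np.unique(cs.labels, return_inverse=True)
    temperature = cfg.temperature0

    history: list[dict] = []
    prev_hard = None
    epochs_run = 0
    for epoch in range(1, cfg.max_joint_epochs + 1):
        epochs_run = epoch
        z_all = _encode_eval(model, data.x_input)
        Q = cc.soft_assign(z_all, centers.value)
        hard = Q.argmax(axis=1)
        # reseed clusters that lost all their cells
        for _ in range(K):
            sizes = np.bincount(hard, minlength=K)
            if sizes.min() > 0:
                break
            j = int(np.argmin(sizes))
            nearest = cc._sq_dists(z_all, centers.value).min(axis=1)
            far = int(np.argmax(nearest))
            logger.info("epoch %d: reseeding empty cluster %d to cell %d",
                        epoch, j, far)
            centers.value = centers.value.copy()
            centers.value[j] = z_all[far]
            Q = cc.soft_assign(z_all, centers.value)
            hard = Q.argmax(axis=1)
        P = cc.target_distribution(Q)

        if prev_hard is not None:
            frac = float((hard != prev_hard).mean())
            if frac < cfg.stop_tol:
                logger.info("epoch %d: converged (%.4f labels changed)",
                            epoch, frac)
                break
        prev_hard = hard

        if use_wce:
            mapping = cons.align_clusters(Q[cs.labeled_idx], cs.labels)
            cols = np.array([mapping.cluster_of(c) for c in classes])

        perm = rng.permutation(n)
        zinb_losses = []
        for bidx in _batches(n, cfg.batch_size, perm):
            z_b = model.encode_t(T.Tensor(data.x_input[bidx]))
            logit_pi, mu, theta = model.decode_t(z_b, data.size_factors[bidx])
            loss = zinb_nll_t(data.x_raw[bidx], logit_pi, mu, theta)
            zinb_losses.append(float(loss.value))
            if cfg.gamma1 > 0:
                sk = cc.soft_kmeans_loss_t(z_b, centers, temperature)
                Q_b = cc.soft_assign_t(z_b, centers)
                kl = cc.kl_loss_t(P[bidx], Q_b)
                loss = loss + cfg.gamma1 * (sk + kl)
            if use_trip:
                tsel = rng.choice(len(cs.triplets),
                                  size=min(cfg.batch_size, len(cs.triplets)),
                                  replace=False)
                trip = cs.triplets[tsel]
                cells, inv = np.unique(trip, return_inverse=True)
                inv = inv.reshape(trip.shape)
                z_t = model.encode_t(T.Tensor(data.x_input[cells]))
                Q_t = cc.soft_assign_t(z_t, centers)
                loss = loss + cfg.gamma2 * cons.triplet_loss_t(
                    T.take_rows(Q_t, inv[:, 0]), T.take_rows(Q_t, inv[:, 1]),
                    T.take_rows(Q_t, inv[:, 2]), cs.margin, cfg.triplet_form)
            if use_pw or use_wce:
                lsel = rng.choice(cs.n_labeled,
                                  size=min(cfg.batch_size, cs.n_labeled),
                                  replace=False)
                z_l = model.encode_t(T.Tensor(data.x_input[cs.labeled_idx[lsel]]))
                Q_l = cc.soft_assign_t(z_l, centers)
                if use_pw:
                    loss = loss + cfg.gamma3 * cons.pairwise_loss_t(
                        Q_l, cs.Y[np.ix_(lsel, lsel)])
                if use_wce:
                    enc_sub = enc_labels[lsel]
                    loss = loss + cfg.gamma4 * cons.weighted_ce_loss_t(
                        Q_l, enc_sub, cols, cs.class_weights[enc_sub])
            if not np.isfinite(loss.value):
                raise RuntimeError(f"non-finite joint loss in epoch {epoch}")
            opt.zero_grad()
            T.backward(loss)
            opt.step()

        history.append(_epoch_log(model, data, centers.value, temperature,
                                  P, cs, cfg, np.mean(zinb_losses), epoch))
        temperature = max(temperature * cfg.temp_decay, cfg.temp_floor)

    z_all = _encode_eval(model, data.x_input)
    Q = cc.soft_assign(z_all, centers.value)
    return FitResult(hard_labels=Q.argmax(axis=1), Q=Q, z=z_all,
                     loss_history=history, epochs_run=epochs_run)


def _epoch_log(model, data, centers, temperature, P, cs, cfg,
               zinb_batch_mean, epoch) -> dict:
    """Full-dataset loss components for the per-epoch log."""
    z = _encode_eval(model, data.x_input)
    Q = cc.soft_assign(z, centers)
    sk, _ = cc.soft_kmeans_loss(z, centers, temperature)
    kl = cc.kl_loss(P, Q)
    rec = {"epoch": epoch, "zinb": float(zinb_batch_mean),
           "soft_kmeans": sk, "kl": kl}
    if len(cs.triplets) > 0:
        rec["triplet"] = cons.triplet_loss(Q, cs.triplets, cs.margin,
                                           cfg.triplet_form)
    if cs.n_labeled > 1:
        Ql = Q[cs.labeled_idx]
        if cs.n_labeled <= 1000:
            rec["pairwise"] = cons.pairwise_loss(
                cons.pairwise_similarity(Ql), cs.Y)
        mapping = cons.align_clusters(Ql, cs.labels)
        rec["wce"] = cons.weighted_ce_loss(Ql, cs.labels, mapping,
                                           cs.class_weights)
    logger.debug("epoch %d: %s", epoch,
                 " ".join(f"{k}={v:.4f}" for k, v in rec.items() if k != "epoch"))
    return rec


# ---------------------------------------------------------------------------
# high-level pipeline and scripted experiments
# ---------------------------------------------------------------------------

def run_pipeline(data: PreprocessedData, K: int,
                 labels: np.ndarray | None = None, r: float = 0.10,
                 n_triplets: int = 10000, margin: float = 0.1,
                 ae_cfg: AEConfig | None = None,
                 cfg: TrainConfig | None = None
                 ) -> tuple[ZINBAutoencoder, FitResult, cons.ConstraintSet]:
    """Preprocess-to-clusters convenience: pretrain, build constraints, fit."""
    cfg = cfg or TrainConfig()
    ae_cfg = ae_cfg or AEConfig()
    model = ZINBAutoencoder(data.x_input.shape[1], ae_cfg, seed=cfg.seed)
    pretrain(model, data, cfg)
    if labels is not None and r > 0:
        cs = cons.build_constraints(labels, r=r, n_triplets=n_triplets,
                                    margin=margin, seed=cfg.seed)
    else:
        cs = cons.empty_constraints()
    result = fit(model, data, cs, K, cfg)
    return model, result, cs


_ARMS = {
    "complete": {},
    "no_triplet": {"gamma2": 0.0},
    "no_pairwise": {"gamma3": 0.0},
    "no_wce": {"gamma4": 0.0},
    "no_label": {"gamma2": 0.0, "gamma3": 0.0, "gamma4": 0.0, "_r": 0.0},
}


def ablation_suite(data: PreprocessedData, labels: np.ndarray, K: int,
                   arms: list[str] | None = None,
                   seeds: list[int] = (0,),
                   cfg: TrainConfig | None = None,
                   r: float = 0.10, n_triplets: int = 10000,
                   fractions: list[float] | None = None,
                   triplet_counts: list[int] | None = None,
                   ae_cfg: AEConfig | None = None) -> pd.DataFrame:
    """Run loss-removal arms and optional labeled-fraction / triplet-count
    sweeps, returning NMI/ARI/AMI/ACC per run."""
    from .metrics import all_metrics

    cfg = cfg or TrainConfig()
    arms = list(arms) if arms is not None else list(_ARMS)
    rows = []

    def one_run(tag, seed, overrides, r_run, n_trip):
        run_cfg = replace(cfg, seed=seed,
                          **{k: v for k, v in overrides.items()
                             if not k.startswith("_")})
        _, res, _ = run_pipeline(data, K, labels=labels, r=r_run,
                                 n_triplets=n_trip, ae_cfg=ae_cfg, cfg=run_cfg)
        rows.append({"arm": tag, "seed": seed,
                     **all_metrics(labels, res.hard_labels)})

    for arm in arms:
        if arm not in _ARMS:
            raise ValueError(f"unknown arm {arm!r}; valid: {list(_ARMS)}")
        overrides = _ARMS[arm]
        r_run = overrides.get("_r", r)
        for seed in seeds:
            one_run(arm, seed, overrides, r_run, n_triplets)
    for frac in (fractions or []):
        for seed in seeds:
            one_run(f"r={frac}", seed, {}, frac, n_triplets)
    for n_trip in (triplet_counts or []):
        for seed in seeds:
            one_run(f"triplets={n_trip}", seed,
                    {} if n_trip > 0 else {"gamma2": 0.0}, r, n_trip)
    return pd.DataFrame(rows)


def grid_search_gamma(data: PreprocessedData, labels: np.ndarray, K: int,
                      values=(0.01, 0.1, 1.0), seeds=(0,),
                      cfg: TrainConfig | None = None,
                      r: float = 0.10, n_triplets: int = 10000
                      ) -> pd.DataFrame:
    """Exhaustive grid over the four loss coefficients (expensive; intended
    for small data or a coarse first pass)."""
    from itertools import product

    from .metrics import all_metrics

    cfg = cfg or TrainConfig()
    rows = []
    for g1, g2, g3, g4 in product(values, repeat=4):
        for seed in seeds:
            run_cfg = replace(cfg, gamma1=g1, gamma2=g2, gamma3=g3,
                              gamma4=g4, seed=seed)
            _, res, _ = run_pipeline(data, K, labels=labels, r=r,
                                     n_triplets=n_triplets, cfg=run_cfg)
            rows.append({"gamma1": g1, "gamma2": g2, "gamma3": g3,
                         "gamma4": g4, "seed": seed,
                         **all_metrics(labels, res.hard_labels)})
    return pd.DataFrame(rows)
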