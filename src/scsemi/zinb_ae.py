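"""ZINB denoising autoencoder.

A symmetric fully connected network (default widths 256-128-32-128-256,
ReLU) maps normalized expression to a latent code z and decodes it to the
three parameter fields of a zero-inflated negative binomial per matrix
entry: dropout probability pi, mean mu (scaled by the cell's size factor so
the likelihood lives on raw counts), and dispersion theta. The
reconstruction loss is the mean ZINB negative log-likelihood, computed in
log space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _tape as T

# clipping bounds keeping every log in the likelihood finite
MU_MIN, MU_MAX = 1e-5, 1e6
THETA_MIN, THETA_MAX = 1e-5, 1e6
PI_LOGIT_MAX = 13.815510557964274  # logit(1 - 1e-6)


@dataclass
class AEConfig:
    layer_widths: tuple = (256, 128, 32, 128, 256)
    activation: str = "relu"
    noise_sd: float = 1.0    # sd of the Gaussian corruption during pretraining
    batch_size: int = 256

    def __post_init__(self):
        w = self.layer_widths
        if len(w) % 2 == 0 or any(w[i] != w[-1 - i] for i in range(len(w) // 2)):
            raise ValueError("layer_widths must be symmetric about the bottleneck")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def bottleneck(self) -> int:
        return self.layer_widths[len(self.layer_widths) // 2]


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters, shape-matched to the input batch."""

    pi: np.ndarray
    mu: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        if not (self.pi.shape == self.mu.shape == self.theta.shape):
            raise ValueError("pi, mu, theta must share one shape")


@dataclass
class EncoderOutput:
    z: np.ndarray


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class ZINBAutoencoder:
    """Holds the network parameters and builds tape graphs for training.

    The encoder is the first half of ``layer_widths`` down to the bottleneck;
    the decoder mirrors it and ends in three linear heads (pi, mu, theta)
    over the gene axis.
    """

    def __init__(self, n_genes: int, cfg: AEConfig | None = None, seed: int = 0):
        self.cfg = cfg or AEConfig()
        self.n_genes = n_genes
        rng = np.random.default_rng(seed)
        widths = list(self.cfg.layer_widths)
        mid = len(widths) // 2
        self._enc_dims = [n_genes] + widths[: mid + 1]
        self._dec_dims = widths[mid:]
        self.params: dict[str, T.Tensor] = {}
        for i in range(len(self._enc_dims) - 1):
            self.params[f"enc_W{i}"] = T.Tensor(
                _glorot(rng, self._enc_dims[i], self._enc_dims[i + 1]),
                requires_grad=True)
            self.params[f"enc_b{i}"] = T.Tensor(
                np.zeros(self._enc_dims[i + 1]), requires_grad=True)
        for i in range(len(self._dec_dims) - 1):
            self.params[f"dec_W{i}"] = T.Tensor(
                _glorot(rng, self._dec_dims[i], self._dec_dims[i + 1]),
                requires_grad=True)
            self.params[f"dec_b{i}"] = T.Tensor(
                np.zeros(self._dec_dims[i + 1]), requires_grad=True)
        last = self._dec_dims[-1]
        for head in ("pi", "mu", "theta"):
            self.params[f"head_W_{head}"] = T.Tensor(
                _glorot(rng, last, n_genes), requires_grad=True)
            self.params[f"head_b_{head}"] = T.Tensor(
                np.zeros(n_genes), requires_grad=True)

    # -- tape graphs ------------------------------------------------------

    def encode_t(self, x: T.Tensor) -> T.Tensor:
        h = x
        n_enc = len(self._enc_dims) - 1
        for i in range(n_enc):
            h = h @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            if i < n_enc - 1:       # bottleneck layer stays linear
                h = T.relu(h)
        return h

    def decode_t(self, z: T.Tensor, size_factors: np.ndarray
                 ) -> tuple[T.Tensor, T.Tensor, T.Tensor]:
        size_factors = np.asarray(size_factors, dtype=np.float64)
        if np.any(size_factors <= 0):
            raise ValueError("size factors must be positive")
        h = z
        for i in range(len(self._dec_dims) - 1):
            h = T.relu(h @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"])
        logit_pi = T.clip(h @ self.params["head_W_pi"] + self.params["head_b_pi"],
                          -PI_LOGIT_MAX, PI_LOGIT_MAX)
        mu_pre = T.clip(h @ self.params["head_W_mu"] + self.params["head_b_mu"],
                        -30.0, 30.0)
        mu = T.clip(T.exp(mu_pre) * T.Tensor(size_factors[:, None]),
                    MU_MIN, MU_MAX)
        th_pre = T.clip(h @ self.params["head_W_theta"] + self.params["head_b_theta"],
                        -30.0, 30.0)
        theta = T.clip(T.exp(th_pre), THETA_MIN, THETA_MAX)
        return logit_pi, mu, theta

    # -- numpy convenience wrappers --------------------------------------

    def encode(self, x_input: np.ndarray, train_mode: bool = False,
               rng: np.random.Generator | None = None) -> EncoderOutput:
        """Encode cells to the latent space.

        In ``train_mode`` (pretraining) the input is corrupted with additive
        zero-mean Gaussian noise of sd ``cfg.noise_sd`` before encoding;
        otherwise the clean input is encoded deterministically.
        """
        x_input = np.asarray(x_input, dtype=np.float64)
        if x_input.ndim != 2 or x_input.shape[1] != self.n_genes:
            raise ValueError(
                f"expected input with {self.n_genes} genes, got shape {x_input.shape}"
            )
        if train_mode and self.cfg.noise_sd > 0:
            rng = rng or np.random.default_rng()
            x_input = x_input + rng.normal(0.0, self.cfg.noise_sd, x_input.shape)
        return EncoderOutput(self.encode_t(T.Tensor(x_input)).value)

    def decode(self, z: EncoderOutput | np.ndarray,
               size_factors: np.ndarray) -> ZINBParams:
        zv = z.z if isinstance(z, EncoderOutput) else np.asarray(z)
        logit_pi, mu, theta = self.decode_t(T.Tensor(zv), size_factors)
        pi = 1.0 / (1.0 + np.exp(-logit_pi.value))
        return ZINBParams(pi=pi, mu=mu.value, theta=theta.value)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].value = np.asarray(v, dtype=np.float64).copy()

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str) -> None:
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def zinb_logpmf(x: np.ndarray, pi: np.ndarray, mu: np.ndarray,
                theta: np.ndarray) -> np.ndarray:
    """Elementwise log P_ZINB(x | pi, mu, theta), numerically stable.

    The zero branch is log(pi + (1-pi) P_NB(0)) evaluated with logaddexp;
    the positive branch uses log-gamma terms of the NB pmf.
    """
    x = np.asarray(x, dtype=np.float64)
    pi = np.clip(np.asarray(pi, dtype=np.float64), 1e-12, 1.0 - 1e-12)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    log_theta_frac = theta * (np.log(theta) - np.log(theta + mu))
    log_nb = (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
              + log_theta_frac + x * (np.log(mu) - np.log(theta + mu)))
    zero_case = np.logaddexp(np.log(pi), np.log1p(-pi) + log_theta_frac)
    return np.where(x == 0, zero_case, np.log1p(-pi) + log_nb)


def zinb_nll(x_raw: np.ndarray, params: ZINBParams) -> float:
    """Mean negative log-likelihood of the counts under the ZINB parameters."""
    for name, arr in (("pi", params.pi), ("mu", params.mu),
                      ("theta", params.theta)):
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"non-finite values in ZINB parameter {name}")
    x_raw = np.asarray(x_raw, dtype=np.float64)
    if x_raw.shape != params.mu.shape:
        raise ValueError("shape mismatch between counts and ZINB parameters")
    return float(-zinb_logpmf(x_raw, params.pi, params.mu, params.theta).mean())


def zinb_nll_t(x_raw: np.ndarray, logit_pi: T.Tensor, mu: T.Tensor,
               theta: T.Tensor) -> T.Tensor:
    """Tape version of the mean ZINB NLL, differentiable in pi/mu/theta.

    log pi and log(1-pi) come from the pi-head logit through softplus, which
    keeps the zero-branch log-sum finite at the clip boundaries.
    """
    x = np.asarray(x_raw, dtype=np.float64)
    log_pi = -T.softplus(-logit_pi)
    log_1mpi = -T.softplus(logit_pi)
    xt = T.Tensor(x)
    log_theta_frac = theta * (T.log(theta) - T.log(theta + mu))
    log_nb = (T.lgamma(xt + theta) - T.lgamma(theta)
              - T.Tensor(gammaln(x + 1.0))
              + log_theta_frac + xt * (T.log(mu) - T.log(theta + mu)))
    zero_case = T.logsumexp2(log_pi, log_1mpi + log_theta_frac)
    mask0 = (x == 0).astype(np.float64)
    ll = T.Tensor(mask0) * zero_case + T.Tensor(1.0 - mask0) * (log_1mpi + log_nb)
    return -T.tmean(ll)
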