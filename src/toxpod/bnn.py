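"""Mean-field variational Bayesian neural network with heteroscedastic output.

One hidden ReLU layer; the output layer has two nodes, the mean and (via a
softplus link) the standard deviation of a Gaussian predictive distribution,
so the network models aleatoric noise per input. Every weight and bias
carries an independent Gaussian variational posterior q(w | mu, sigma) with
sigma = softplus(rho); the prior is a scale mixture of two zero-mean normals
(one wide, one narrow), which behaves like a soft spike-and-slab. Training
minimizes the negative ELBO

    KL(q || prior)  -  E_q[ log N(y | mean(x, w), sd(x, w)) ]

with the KL term estimated by Monte Carlo using the same reparameterized
weight samples as the likelihood term. Gradients are computed analytically
(reparameterization trick); with Gaussian q the direct d(log q)/d(mu) term
cancels against the pathwise one, and the rho gradient collapses to
``(g_w * eps - 1/sigma) * sigmoid(rho)`` where g_w is the gradient of the
remaining loss terms with respect to the sampled weight.

Predictions are Monte Carlo: each draw samples weights from q, then a target
from the Gaussian output, mixing epistemic (weight) and aleatoric (output-SD)
variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from toxpod.uacqr import IntervalPrediction

_LOG_2PI = math.log(2.0 * math.pi)
_SD_FLOOR = 1e-4


@dataclass
class BNNConfig:
    n_hidden: int = 128
    prior_pi: float = 0.5
    prior_sigma1: float = 1.0
    prior_sigma2: float = 0.0025
    learning_rate: float = 0.01
    n_epochs: int = 600
    mc_train_samples: int = 1
    predict_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_pi < 1.0):
            raise ValueError("prior_pi must lie in (0, 1)")
        if not (self.prior_sigma1 > self.prior_sigma2 > 0.0):
            raise ValueError("need prior_sigma1 > prior_sigma2 > 0 (wide + narrow)")
        if self.predict_samples < 2:
            raise ValueError("predict_samples must be >= 2")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softplus_inv(y: float) -> float:
    return math.log(math.expm1(y)) if y < 30 else y


@dataclass
class PosteriorParams:
    """Variational means/rhos for each layer plus training metadata."""

    mu: dict
    rho: dict
    config: BNNConfig
    n_features: int
    loss_history: np.ndarray = field(default=None, repr=False)

    def sigma(self, name: str) -> np.ndarray:
        return _softplus(self.rho[name])


@dataclass
class PredictiveSamples:
    """Monte-Carlo draws from the predictive distribution, one row per chemical."""

    chem_ids: list
    draws: np.ndarray  # (n_chems, n_draws)


def _neg_log_prior_grad(w: np.ndarray, cfg: BNNConfig) -> np.ndarray:
    """d(-log P(w))/dw for the two-component scale-mixture prior."""
    s1, s2, pi = cfg.prior_sigma1, cfg.prior_sigma2, cfg.prior_pi
    # densities up to the shared 1/sqrt(2 pi) factor
    n1 = np.exp(-0.5 * (w / s1) ** 2) / s1
    n2 = np.exp(-0.5 * (w / s2) ** 2) / s2
    denom = pi * n1 + (1.0 - pi) * n2 + 1e-300
    return w * (pi * n1 / s1**2 + (1.0 - pi) * n2 / s2**2) / denom


def _neg_log_prior(w: np.ndarray, cfg: BNNConfig) -> float:
    s1, s2, pi = cfg.prior_sigma1, cfg.prior_sigma2, cfg.prior_pi
    n1 = np.exp(-0.5 * (w / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    n2 = np.exp(-0.5 * (w / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return float(-np.log(pi * n1 + (1.0 - pi) * n2 + 1e-300).sum())


def _forward(X, y, w):
    """Forward pass + NLL and its gradients w.r.t. each sampled weight tensor."""
    z = X @ w["W1"] + w["b1"]
    h = np.maximum(z, 0.0)
    o = h @ w["W2"] + w["b2"]
    mean = o[:, 0]
    raw = o[:, 1]
    sd = _softplus(raw) + _SD_FLOOR
    resid = y - mean
    nll = float(np.sum(0.5 * _LOG_2PI + np.log(sd) + 0.5 * (resid / sd) ** 2))

    d_mean = -resid / sd**2
    d_raw = (1.0 / sd - resid**2 / sd**3) * _sigmoid(raw)
    do = np.stack([d_mean, d_raw], axis=1)
    grads = {
        "W2": h.T @ do,
        "b2": do.sum(axis=0),
    }
    dh = do @ w["W2"].T
    dz = dh * (z > 0)
    grads["W1"] = X.T @ dz
    grads["b1"] = dz.sum(axis=0)
    return nll, grads, mean, sd


def fit_bnn(X, y, config: Optional[BNNConfig] = None) -> PosteriorParams:
    """Train by Bayes-by-backprop with Adam; reproducible given config.seed.

    Raises RuntimeError naming the epoch if the loss becomes non-finite.
    """
    cfg = config or BNNConfig()
    Xa = np.asarray(getattr(X, "values", X), dtype=float)
    ya = np.asarray(y, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    n, d = Xa.shape
    if n < 2:
        raise ValueError("need at least 2 training points")
    if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
        raise ValueError("features and targets must be finite")

    rng = np.random.default_rng(cfg.seed)
    h = cfg.n_hidden
    mu = {
        "W1": rng.normal(0.0, math.sqrt(2.0 / d), size=(d, h)),
        "b1": np.zeros(h),
        "W2": rng.normal(0.0, math.sqrt(2.0 / h), size=(h, 2)),
        "b2": np.array([float(ya.mean()), _softplus_inv(max(float(ya.std()), 0.05))]),
    }
    rho = {k: np.full_like(v, -5.0) for k, v in mu.items()}

    adam_m = {k: np.zeros_like(v) for k, v in mu.items()}
    adam_v = {k: np.zeros_like(v) for k, v in mu.items()}
    adam_m_r = {k: np.zeros_like(v) for k, v in rho.items()}
    adam_v_r = {k: np.zeros_like(v) for k, v in rho.items()}
    b1m, b2m, eps_adam = 0.9, 0.999, 1e-8

    losses = np.empty(cfg.n_epochs)
    for epoch in range(cfg.n_epochs):
        g_mu = {k: np.zeros_like(v) for k, v in mu.items()}
        g_rho = {k: np.zeros_like(v) for k, v in rho.items()}
        loss = 0.0
        for _ in range(cfg.mc_train_samples):
            eps = {k: rng.standard_normal(v.shape) for k, v in mu.items()}
            sig = {k: _softplus(rho[k]) for k in rho}
            w = {k: mu[k] + sig[k] * eps[k] for k in mu}
            nll, g_w, _, _ = _forward(Xa, ya, w)
            loss += nll
            for k in mu:
                gw = g_w[k] + _neg_log_prior_grad(w[k], cfg)
                loss += _neg_log_prior(w[k], cfg)
                # + log q(w): MC estimate of the entropy part of the KL; its
                # gradient is folded analytically into g_mu/g_rho below
                loss += float(
                    np.sum(-0.5 * _LOG_2PI - np.log(sig[k]) - 0.5 * eps[k] ** 2)
                )
                g_mu[k] += gw
                g_rho[k] += (gw * eps[k] - 1.0 / sig[k]) * _sigmoid(rho[k])
        loss /= cfg.mc_train_samples
        if not math.isfinite(loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        losses[epoch] = loss

        t = epoch + 1
        lr_t = cfg.learning_rate * math.sqrt(1 - b2m**t) / (1 - b1m**t)
        for k in mu:
            for params, grads, am, av in (
                (mu, g_mu, adam_m, adam_v),
                (rho, g_rho, adam_m_r, adam_v_r),
            ):
                g = grads[k] / cfg.mc_train_samples
                am[k] = b1m * am[k] + (1 - b1m) * g
                av[k] = b2m * av[k] + (1 - b2m) * g**2
                params[k] -= lr_t * am[k] / (np.sqrt(av[k]) + eps_adam)

    return PosteriorParams(mu, rho, cfg, d, losses)


def sample_predictions(
    post: PosteriorParams,
    X,
    n_draws: Optional[int] = None,
    seed: int = 0,
    chem_ids: Optional[Sequence[str]] = None,
) -> PredictiveSamples:
    """Draw from the predictive distribution: weights from q, then the Gaussian output."""
    n_draws = post.config.predict_samples if n_draws is None else n_draws
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    Xa = np.asarray(getattr(X, "values", X), dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if chem_ids is None:
        chem_ids = list(getattr(X, "chem_ids", [str(i) for i in range(Xa.shape[0])]))
    rng = np.random.default_rng(seed)
    draws = np.empty((Xa.shape[0], n_draws))
    sig = {k: _softplus(post.rho[k]) for k in post.rho}
    for j in range(n_draws):
        w = {
            k: post.mu[k] + sig[k] * rng.standard_normal(post.mu[k].shape)
            for k in post.mu
        }
        z = np.maximum(Xa @ w["W1"] + w["b1"], 0.0)
        o = z @ w["W2"] + w["b2"]
        mean, sd = o[:, 0], _softplus(o[:, 1]) + _SD_FLOOR
        draws[:, j] = mean + sd * rng.standard_normal(mean.shape)
    return PredictiveSamples(list(chem_ids), draws)


def predictive_moments(post: PosteriorParams, X, n_draws: int = 500, seed: int = 0):
    """Mean prediction and mean aleatoric SD, averaged over weight samples."""
    Xa = np.asarray(getattr(X, "values", X), dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    rng = np.random.default_rng(seed)
    sig = {k: _softplus(post.rho[k]) for k in post.rho}
    means = np.zeros(Xa.shape[0])
    sds = np.zeros(Xa.shape[0])
    for _ in range(n_draws):
        w = {
            k: post.mu[k] + sig[k] * rng.standard_normal(post.mu[k].shape)
            for k in post.mu
        }
        z = np.maximum(Xa @ w["W1"] + w["b1"], 0.0)
        o = z @ w["W2"] + w["b2"]
        means += o[:, 0]
        sds += _softplus(o[:, 1]) + _SD_FLOOR
    return means / n_draws, sds / n_draws


def summarize_predictive(
    samples: PredictiveSamples, level: float = 0.95
) -> list[IntervalPrediction]:
    """Percentile summary of the draws (linear interpolation between order stats).

    The reported sigma is the SD of the draws, i.e. total predictive SD.
    """
    if samples.draws.shape[1] < 2:
        raise ValueError("need at least 2 draws")
    alpha = 1.0 - level
    lo, med, hi = np.percentile(
        samples.draws, [100 * alpha / 2.0, 50.0, 100 * (1 - alpha / 2.0)], axis=1
    )
    sd = samples.draws.std(axis=1)
    return [
        IntervalPrediction(
            str(cid),
            float(np.clip(med[i], lo[i], hi[i])),
            float(lo[i]),
            float(hi[i]),
            level,
            sigma=float(sd[i]),
        )
        for i, cid in enumerate(samples.chem_ids)
    ]
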