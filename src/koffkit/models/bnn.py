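"""Bayesian neural network regressor trained by mean-field variational inference.

The weight posterior is approximated by fully factorized Gaussians
``q(w) = N(mu, softplus(rho)^2)`` over every weight and bias of a small
multilayer perceptron (default: one hidden layer of 16 sigmoid units).  The
observation model is Gaussian with a single learnable noise scale
(log-parameterized).  Training minimizes the negative evidence lower bound

    -ELBO = E_q[-log p(y | x, w)] + KL(q(w) || N(0, prior_std^2))

by stochastic gradient descent with the reparameterization trick
(``w = mu + softplus(rho) * eps``) and the Adam optimizer; the KL term is
computed in closed form.  Gradients are derived by hand-coded backpropagation
so the model has no autodiff dependency.

Inputs and targets are standardized internally for optimizer conditioning;
predictions are returned on the original scale.  All randomness flows from
``BNNConfig.seed``, so repeated fits/predictions are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["BNNConfig", "BNNDivergenceError", "BNNRegressor", "PosteriorPrediction"]


class BNNDivergenceError(RuntimeError):
    """Raised when the ELBO objective becomes non-finite during training."""


@dataclass
class BNNConfig:
    hidden_layer_sizes: tuple[int, ...] = (16,)
    activation: str = "sigmoid"  # sigmoid | tanh | relu
    prior_std: float = 1.0
    learning_rate: float = 1e-2
    epochs: int = 2000
    elbo_mc_samples: int = 1
    posterior_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layer_sizes = tuple(int(h) for h in self.hidden_layer_sizes)
        if any(h < 1 for h in self.hidden_layer_sizes) or not self.hidden_layer_sizes:
            raise ValueError("hidden_layer_sizes must be non-empty, all >= 1")
        if self.prior_std <= 0:
            raise ValueError("prior_std must be > 0")
        if min(self.epochs, self.elbo_mc_samples, self.posterior_samples) < 1:
            raise ValueError("epochs, elbo_mc_samples and posterior_samples must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class PosteriorPrediction:
    """Posterior-predictive summary: mean and central 95% interval per sample."""

    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    draws: np.ndarray | None = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' given (z, a=f(z)))
    "sigmoid": (_sigmoid, lambda z, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
}

_RHO_INIT = -3.0  # softplus(-3) ~ 0.049: small but trainable initial posterior std


class BNNRegressor:
    """Mean-field variational BNN with a scikit-learn-like fit/predict surface.

    Attributes set by :meth:`fit`: ``elbo_initial_`` and ``elbo_final_``
    (each averaged over >= 100 Monte Carlo draws), ``n_features_in_``.
    """

    def __init__(self, config: BNNConfig | None = None, **overrides):
        if config is None:
            config = BNNConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a config or keyword overrides, not both")
        self.config = config
        self._params: list[np.ndarray] | None = None

    # -- parameter bookkeeping ---------------------------------------------
    # Flat parameter list: per layer [W_mu, W_rho, b_mu, b_rho], then the
    # scalar log noise as the final entry.

    def _init_params(self, d_in: int, rng: np.random.Generator) -> list[np.ndarray]:
        sizes = [d_in, *self.config.hidden_layer_sizes, 1]
        params: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            params.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
            params.append(np.full((fan_in, fan_out), _RHO_INIT))
            params.append(np.zeros(fan_out))
            params.append(np.full(fan_out, _RHO_INIT))
        params.append(np.zeros(()))  # log sigma_noise
        return params

    def _n_layers(self) -> int:
        return len(self.config.hidden_layer_sizes) + 1

    @staticmethod
    def _sample_eps(params: list[np.ndarray], rng: np.random.Generator) -> list[np.ndarray]:
        return [rng.standard_normal(p.shape) for p in params[:-1]]

    # -- objective ----------------------------------------------------------

    def _forward(self, X: np.ndarray, params: list[np.ndarray], eps: list[np.ndarray]):
        """Forward pass with one reparameterized weight sample; returns caches."""
        act, _ = _ACTIVATIONS[self.config.activation]
        caches = []
        a = X
        for layer in range(self._n_layers()):
            w_mu, w_rho, b_mu, b_rho = params[4 * layer : 4 * layer + 4]
            e_w, e_b = eps[4 * layer], eps[4 * layer + 2]
            s_w, s_b = _softplus(w_rho), _softplus(b_rho)
            w = w_mu + s_w * e_w
            b = b_mu + s_b * e_b
            z = a @ w + b
            last = layer == self._n_layers() - 1
            a_next = z if last else act(z)
            caches.append((a, z, a_next, w))
            a = a_next
        return a[:, 0], caches

    def _kl(self, params: list[np.ndarray]) -> float:
        p = self.config.prior_std
        total = 0.0
        for layer in range(self._n_layers()):
            for mu, rho in (
                (params[4 * layer], params[4 * layer + 1]),
                (params[4 * layer + 2], params[4 * layer + 3]),
            ):
                s = _softplus(rho)
                total += float(
                    np.sum(np.log(p / s) + (s * s + mu * mu) / (2.0 * p * p) - 0.5)
                )
        return total

    def _elbo(
        self, X: np.ndarray, y: np.ndarray, n_draws: int, rng: np.random.Generator
    ) -> float:
        """ELBO estimate averaged over ``n_draws`` weight samples."""
        params = self._params
        sigma = float(np.exp(params[-1]))
        n = X.shape[0]
        kl = self._kl(params)
        nll = 0.0
        for _ in range(n_draws):
            out, _ = self._forward(X, params, self._sample_eps(params, rng))
            resid = y - out
            nll += 0.5 * n * np.log(2.0 * np.pi) + n * np.log(sigma) + 0.5 * np.sum(
                resid**2
            ) / (sigma * sigma)
        return -(nll / n_draws) - kl

    def _loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, list[np.ndarray]]:
        """Negative-ELBO estimate and gradients via local reparameterization.

        Pre-activations are sampled from their induced Gaussians
        ``z ~ N(a.W_mu + b_mu, a^2.sigma_W^2 + sigma_b^2)`` instead of
        sampling every weight, which leaves the ELBO expectation unchanged
        but sharply reduces gradient variance.
        """
        params = self._params
        cfg = self.config
        act, dact = _ACTIVATIONS[cfg.activation]
        n = X.shape[0]
        sigma = float(np.exp(params[-1]))
        grads = [np.zeros_like(p) for p in params]

        nll_total = 0.0
        for _ in range(cfg.elbo_mc_samples):
            a = X
            caches = []
            for layer in range(self._n_layers()):
                w_mu, w_rho, b_mu, b_rho = params[4 * layer : 4 * layer + 4]
                s_w, s_b = _softplus(w_rho), _softplus(b_rho)
                mean_z = a @ w_mu + b_mu
                std_z = np.sqrt((a * a) @ (s_w * s_w) + s_b * s_b)
                eps = rng.standard_normal(mean_z.shape)
                z = mean_z + std_z * eps
                last = layer == self._n_layers() - 1
                a_next = z if last else act(z)
                caches.append((a, z, a_next, std_z, eps, w_mu, s_w, s_b))
                a = a_next
            out = a[:, 0]
            resid = out - y
            nll_total += (
                0.5 * n * np.log(2.0 * np.pi)
                + n * np.log(sigma)
                + 0.5 * np.sum(resid**2) / (sigma * sigma)
            )
            # d NLL / d log_sigma = n - sum(r^2)/sigma^2
            grads[-1] += (n - np.sum(resid**2) / (sigma * sigma)) / cfg.elbo_mc_samples

            delta = (resid / (sigma * sigma))[:, None]  # d NLL / d out
            scale = 1.0 / cfg.elbo_mc_samples
            for layer in range(self._n_layers() - 1, -1, -1):
                a_in, z, a_out, std_z, eps, w_mu, s_w, s_b = caches[layer]
                if layer != self._n_layers() - 1:
                    delta = delta * dact(z, a_out)
                ge = delta * eps / std_z  # d NLL / d var_z, times 2*std_z
                w_rho, b_rho = params[4 * layer + 1], params[4 * layer + 3]
                grads[4 * layer] += (a_in.T @ delta) * scale
                grads[4 * layer + 1] += (
                    ((a_in * a_in).T @ ge) * s_w * _sigmoid(w_rho) * scale
                )
                grads[4 * layer + 2] += delta.sum(axis=0) * scale
                grads[4 * layer + 3] += ge.sum(axis=0) * s_b * _sigmoid(b_rho) * scale
                delta = delta @ w_mu.T + (ge @ (s_w * s_w).T) * a_in

        # closed-form KL gradients
        p2 = cfg.prior_std * cfg.prior_std
        for layer in range(self._n_layers()):
            for mu_i, rho_i in ((4 * layer, 4 * layer + 1), (4 * layer + 2, 4 * layer + 3)):
                mu, rho = params[mu_i], params[rho_i]
                s = _softplus(rho)
                grads[mu_i] += mu / p2
                grads[rho_i] += (s / p2 - 1.0 / s) * _sigmoid(rho)

        loss = nll_total / cfg.elbo_mc_samples + self._kl(params)
        return float(loss), grads

    # -- training -----------------------------------------------------------

    def fit(self, X, y) -> "BNNRegressor":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")

        self.n_features_in_ = X.shape[1]
        self._x_mean = X.mean(axis=0)
        self._x_scale = X.std(axis=0)
        self._x_scale[self._x_scale < 1e-12] = 1.0
        self._y_mean = float(y.mean())
        self._y_scale = float(y.std())
        if self._y_scale < 1e-12:
            self._y_scale = 1.0
        Xs = (X - self._x_mean) / self._x_scale
        ys = (y - self._y_mean) / self._y_scale

        rng = np.random.default_rng(cfg.seed)
        self._params = self._init_params(X.shape[1], rng)
        elbo_rng = np.random.default_rng([cfg.seed, 0xE1B0])
        self.elbo_initial_ = self._elbo(Xs, ys, max(100, cfg.elbo_mc_samples), elbo_rng)

        m = [np.zeros_like(p) for p in self._params]
        v = [np.zeros_like(p) for p in self._params]
        b1, b2, eps_adam = 0.9, 0.999, 1e-8
        for t in range(1, cfg.epochs + 1):
            with np.errstate(over="ignore", invalid="ignore"):
                loss, grads = self._loss_and_grads(Xs, ys, rng)
            if not np.isfinite(loss):
                raise BNNDivergenceError(
                    f"non-finite loss at epoch {t}; try a smaller learning rate"
                )
            for i, g in enumerate(grads):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                m_hat = m[i] / (1 - b1**t)
                v_hat = v[i] / (1 - b2**t)
                self._params[i] = self._params[i] - cfg.learning_rate * m_hat / (
                    np.sqrt(v_hat) + eps_adam
                )

        elbo_rng = np.random.default_rng([cfg.seed, 0xE1B1])
        self.elbo_final_ = self._elbo(Xs, ys, max(100, cfg.elbo_mc_samples), elbo_rng)
        return self

    # -- prediction ---------------------------------------------------------

    def _check_ready(self, X) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("fit the model before predicting")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got shape {X.shape}"
            )
        return (X - self._x_mean) / self._x_scale

    def predict(self, X) -> np.ndarray:
        """Posterior-predictive mean (average over sampled weight draws)."""
        Xs = self._check_ready(X)
        rng = np.random.default_rng([self.config.seed, 0x9E3D])
        total = np.zeros(Xs.shape[0])
        for _ in range(self.config.posterior_samples):
            out, _ = self._forward(Xs, self._params, self._sample_eps(self._params, rng))
            total += out
        mean = total / self.config.posterior_samples
        return mean * self._y_scale + self._y_mean

    def predict_posterior(self, X, include_draws: bool = True) -> PosteriorPrediction:
        """Full posterior-predictive draws (weight samples + likelihood noise).

        ``lower95``/``upper95`` are the empirical 2.5%/97.5% quantiles of the
        draws; with a single draw the interval is degenerate at that draw.
        """
        Xs = self._check_ready(X)
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 0x9E3E])
        sigma = float(np.exp(self._params[-1]))
        draws = np.empty((cfg.posterior_samples, Xs.shape[0]))
        for s in range(cfg.posterior_samples):
            out, _ = self._forward(Xs, self._params, self._sample_eps(self._params, rng))
            draws[s] = out + sigma * rng.standard_normal(Xs.shape[0])
        draws = draws * self._y_scale + self._y_mean
        mean = draws.mean(axis=0)
        lower = np.quantile(draws, 0.025, axis=0)
        upper = np.quantile(draws, 0.975, axis=0)
        return PosteriorPrediction(
            mean=mean,
            lower95=np.minimum(lower, mean),
            upper95=np.maximum(upper, mean),
            draws=draws if include_draws else None,
        )

    @property
    def noise_scale_(self) -> float:
        """Learned likelihood noise standard deviation, on the target scale."""
        if self._params is None:
            raise RuntimeError("fit the model first")
        return float(np.exp(self._params[-1])) * self._y_scale
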