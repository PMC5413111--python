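"""The feedforward channel: weights, gain nonlinearity, noise, spiking.

The second-layer response is ``y = g(W x + zeta) + eta`` with pre-threshold
noise ``zeta`` (covariance ``Sigma_zeta``) and output noise ``eta``
(covariance ``Sigma_eta``).  Around the mean drive ``h = W f(s)`` the
channel linearizes to effective weights ``W_eff = Gbar' W``, where ``Gbar'``
is the diagonal matrix of average gain slopes: the derivative with respect
to ``h_i`` of ``E[g(h_i + chi_i)]`` with ``chi = W xi + zeta`` the total
pre-nonlinearity noise.  A nonlinear gain additionally contributes the
excess covariance

    delta_Sigma_g = Cov[g(h + chi)] - Gbar' Sigma_chi Gbar',

which vanishes for linear ``g`` and is positive semi-definite whenever
``chi`` is Gaussian, so it can be folded into the effective output noise

    Sigma_eff_eta = Gbar' Sigma_zeta Gbar' + delta_Sigma_g + Sigma_eta.

The dichotomized-Gaussian (DG) spiking model is the extreme case
``g = Heaviside``: ``y_i = 1`` iff ``x_i + zeta_i >= theta_i``.  Its mean is
the Gaussian CDF ``mu_i(s) = Phi((f_i(s) - theta_i) / sigma_i(s))``; its
covariance has no convenient closed form and is estimated by Monte Carlo,
from which the output information is ``mu'^T Cov^-1 mu'``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm

__all__ = [
    "Gain",
    "LinearGain",
    "StepGain",
    "CallableGain",
    "ChannelSpec",
    "EffectiveChannel",
    "DeltaSigmaResult",
    "McFisherEstimate",
    "mean_drive",
    "effective_weights",
    "delta_sigma_g",
    "effective_channel",
    "dg_mean",
    "dg_thresholds",
    "dg_sample",
    "mc_fisher",
]

logger = logging.getLogger(__name__)

# Gauss-Hermite (probabilists') nodes for Gaussian-smoothed gain statistics
_GH_NODES, _GH_WEIGHTS = hermegauss(101)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


class Gain:
    """Scalar gain nonlinearity applied componentwise.

    Subclasses implement ``__call__`` (vectorized) and may override the
    Gaussian-smoothed statistics with closed forms.  The generic smoothed
    slope uses Stein's identity ``d/dh E[g(h + s z)] = E[z g(h + s z)] / s``
    (z standard normal), evaluated by Gauss-Hermite quadrature, which is
    valid even for discontinuous gains such as the spiking step.
    """

    def __call__(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def slope(self, x: np.ndarray) -> np.ndarray:
        """Pointwise derivative g'(x); needed only when the input noise is zero."""
        raise NotImplementedError(
            f"{type(self).__name__} has no analytic derivative; "
            "provide nonzero smoothing noise"
        )

    def smoothed_mean(self, h: np.ndarray, sd: np.ndarray) -> np.ndarray:
        """``gbar(h) = E[g(h + sd * z)]``, elementwise in ``h``."""
        h = np.asarray(h, dtype=float)
        sd = np.broadcast_to(np.asarray(sd, dtype=float), h.shape)
        vals = self(h[..., None] + sd[..., None] * _GH_NODES)
        return vals @ _GH_WEIGHTS

    def smoothed_slope(self, h: np.ndarray, sd: np.ndarray) -> np.ndarray:
        """``gbar'(h) = d/dh E[g(h + sd * z)]``, elementwise in ``h``."""
        h = np.asarray(h, dtype=float)
        sd = np.broadcast_to(np.asarray(sd, dtype=float), h.shape)
        out = np.empty_like(h)
        noisy = sd > 0
        if np.any(noisy):
            vals = self(h[noisy, None] + sd[noisy, None] * _GH_NODES)
            out[noisy] = (vals * _GH_NODES) @ _GH_WEIGHTS / sd[noisy]
        if np.any(~noisy):
            out[~noisy] = self.slope(h[~noisy])
        return out


class LinearGain(Gain):
    """``g(x) = slope * x + intercept`` (smoothing leaves the slope unchanged)."""

    def __init__(self, slope: float = 1.0, intercept: float = 0.0) -> None:
        self._slope, self._intercept = float(slope), float(intercept)

    def __call__(self, x):
        return self._slope * np.asarray(x, float) + self._intercept

    def slope(self, x):
        return np.full_like(np.asarray(x, float), self._slope)

    def smoothed_mean(self, h, sd):
        return self(h)

    def smoothed_slope(self, h, sd):
        return self.slope(h)


class StepGain(Gain):
    """Heaviside spiking gain ``g(x) = 1[x >= threshold]``.

    Under Gaussian smoothing of scale ``sd`` the mean is
    ``Phi((h - threshold)/sd)`` and the slope the corresponding normal
    density.
    """

    def __init__(self, threshold: float = 0.0) -> None:
        self.threshold = float(threshold)

    def __call__(self, x):
        return (np.asarray(x, float) >= self.threshold).astype(float)

    def smoothed_mean(self, h, sd):
        h = np.asarray(h, float)
        sd = np.broadcast_to(np.asarray(sd, float), h.shape)
        with np.errstate(divide="ignore"):
            z = np.where(sd > 0, (h - self.threshold) / np.where(sd > 0, sd, 1.0), np.inf)
        out = norm.cdf(z)
        zero = sd == 0
        if np.any(zero):
            out[zero] = self(h[zero])
        return out

    def smoothed_slope(self, h, sd):
        h = np.asarray(h, float)
        sd = np.broadcast_to(np.asarray(sd, float), h.shape)
        if np.any(sd <= 0):
            raise ValueError("step gain has no slope without smoothing noise")
        return norm.pdf((h - self.threshold) / sd) / sd

    def slope(self, x):
        raise ValueError("step gain has no pointwise derivative")


class CallableGain(Gain):
    """Wrap an arbitrary vectorized callable as a gain."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray],
                 deriv: Optional[Callable[[np.ndarray], np.ndarray]] = None) -> None:
        self._fn, self._deriv = fn, deriv

    def __call__(self, x):
        return np.asarray(self._fn(np.asarray(x, float)), dtype=float)

    def slope(self, x):
        if self._deriv is None:
            return super().slope(x)
        return np.asarray(self._deriv(np.asarray(x, float)), dtype=float)


@dataclass
class ChannelSpec:
    """Static description of the second-layer transformation."""

    weights: np.ndarray
    gain: Gain
    sigma_zeta: np.ndarray  # pre-threshold noise covariance (may be zeros)
    sigma_eta: np.ndarray  # output noise covariance
    thresholds: Optional[np.ndarray] = None  # DG spiking thresholds


@dataclass
class EffectiveChannel:
    """Linearization of a channel around the mean drive at one stimulus."""

    w_eff: np.ndarray
    h: np.ndarray
    gbar_prime: np.ndarray  # diagonal of Gbar'
    delta_sigma_g: np.ndarray
    sigma_eff_eta: np.ndarray


@dataclass
class DeltaSigmaResult:
    """Monte-Carlo estimate of the nonlinearity's excess covariance."""

    matrix: np.ndarray
    min_eigenvalue: float
    min_eigenvalue_se: float
    n_samples: int


@dataclass
class McFisherEstimate:
    value: float
    se: float
    n_draws: int


def mean_drive(weights: np.ndarray, f_values: np.ndarray) -> np.ndarray:
    """``h(s) = W f(s)``."""
    w = np.asarray(weights, dtype=float)
    f = np.asarray(f_values, dtype=float)
    if w.ndim != 2 or w.shape[1] != f.shape[0]:
        raise ValueError(f"shape mismatch: W is {w.shape}, f has length {f.shape[0]}")
    return w @ f


def effective_weights(
    weights: np.ndarray, gain: Gain, h: np.ndarray, sigma_chi: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Average-slope effective weights ``(W_eff, diag(Gbar'))``.

    ``sigma_chi = W Sigma_xi W^T + Sigma_zeta`` is the covariance of the
    total noise entering the nonlinearity; only its diagonal (the marginal
    scales) matters for the average slopes.
    """
    w = np.asarray(weights, dtype=float)
    sd = np.sqrt(np.clip(np.diag(np.asarray(sigma_chi, float)), 0.0, None))
    gbar_prime = gain.smoothed_slope(np.asarray(h, float), sd)
    if not np.all(np.isfinite(gbar_prime)):
        raise ValueError("non-finite average-slope estimate")
    return gbar_prime[:, None] * w, gbar_prime


def delta_sigma_g(
    gain: Gain,
    h: np.ndarray,
    sigma_chi: np.ndarray,
    mc_samples: int,
    rng: np.random.Generator,
) -> DeltaSigmaResult:
    """Estimate ``delta_Sigma_g = Cov[g(h + chi)] - Gbar' Sigma_chi Gbar'``.

    ``chi`` is drawn Gaussian with covariance ``sigma_chi`` (the regime in
    which the excess covariance is provably PSD).  The result is
    symmetrized and reported with its minimum eigenvalue and the Monte-Carlo
    standard error of that eigenvalue's quadratic form.
    """
    if mc_samples < 1000:
        raise ValueError("mc_samples must be >= 1000 for a meaningful estimate")
    h = np.atleast_1d(np.asarray(h, dtype=float))
    sigma_chi = np.atleast_2d(np.asarray(sigma_chi, dtype=float))
    eigvals, eigvecs = np.linalg.eigh(0.5 * (sigma_chi + sigma_chi.T))
    if eigvals[0] < -1e-10 * max(eigvals[-1], 1.0):
        raise ValueError("sigma_chi must be positive semi-definite")
    factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    chi = rng.standard_normal((mc_samples, h.shape[0])) @ factor.T
    y = gain(h[None, :] + chi)
    cov_y = np.cov(y, rowvar=False).reshape(h.shape[0], h.shape[0])
    gbar_prime = gain.smoothed_slope(h, np.sqrt(np.clip(np.diag(sigma_chi), 0, None)))
    linear_part = gbar_prime[:, None] * sigma_chi * gbar_prime[None, :]
    delta = 0.5 * ((cov_y - linear_part) + (cov_y - linear_part).T)
    w_min, v = np.linalg.eigh(delta)
    vmin = v[:, 0]
    # SE of v^T Cov[y] v: sample variance of the squared projections
    proj = (y - y.mean(axis=0)) @ vmin
    se = float(np.std(proj**2, ddof=1) / math.sqrt(mc_samples))
    return DeltaSigmaResult(
        matrix=delta,
        min_eigenvalue=float(w_min[0]),
        min_eigenvalue_se=se,
        n_samples=mc_samples,
    )


def effective_channel(
    spec: ChannelSpec,
    f_values: np.ndarray,
    sigma_xi: np.ndarray,
    mc_samples: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> EffectiveChannel:
    """Linearize a channel at one stimulus: W_eff, delta_Sigma_g, Sigma_eff_eta."""
    w = np.asarray(spec.weights, dtype=float)
    h = mean_drive(w, f_values)
    sigma_chi = w @ np.asarray(sigma_xi, float) @ w.T + np.asarray(spec.sigma_zeta, float)
    w_eff, gbar = effective_weights(w, spec.gain, h, sigma_chi)
    if isinstance(spec.gain, LinearGain):
        delta = np.zeros_like(sigma_chi)
    else:
        if rng is None:
            raise ValueError("nonlinear gain requires an rng for the MC estimate")
        delta = delta_sigma_g(spec.gain, h, sigma_chi, mc_samples, rng).matrix
    gz = gbar[:, None] * np.asarray(spec.sigma_zeta, float) * gbar[None, :]
    sigma_eff = gz + delta + np.asarray(spec.sigma_eta, float)
    return EffectiveChannel(
        w_eff=w_eff, h=h, gbar_prime=gbar, delta_sigma_g=delta, sigma_eff_eta=sigma_eff
    )


def dg_mean(f_value, threshold, input_sd):
    """DG firing probability ``Phi((f - theta) / sigma)`` (vectorized)."""
    sd = np.asarray(input_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("input standard deviation must be > 0")
    return norm.cdf((np.asarray(f_value, float) - np.asarray(threshold, float)) / sd)


def dg_thresholds(baseline: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Default spiking thresholds: 3/4 of each cell's peak rate ``rho + upsilon``."""
    return 0.75 * (np.asarray(baseline, float) + np.asarray(amplitude, float))


def dg_sample(
    f_values: np.ndarray,
    thresholds: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    sigma_xi: Optional[np.ndarray] = None,
    rank1: Optional[Tuple[float, float, np.ndarray]] = None,
    sigma_zeta2: float = 0.0,
) -> np.ndarray:
    """Draw binary DG responses ``y_i = 1[x_i + zeta_i >= theta_i]``.

    The latent input is ``x ~ N(f, Sigma_xi)``.  When ``rank1 = (gamma_u,
    eps, u)`` is given, ``Sigma_xi = gamma_u * diag(f) + eps * u u^T`` is
    sampled in structured form ``x = f + sqrt(gamma_u) * sqrt(f) * z +
    sqrt(eps) * w * u`` (z an iid standard-normal vector, w a scalar), which
    avoids factorizing the dense matrix; a negative ``eps`` falls back to a
    dense eigen-factorization.  ``sigma_zeta2`` adds iid Gaussian
    pre-threshold noise.  Returns an ``(n_draws, n)`` float matrix of 0/1.
    """
    f = np.asarray(f_values, dtype=float)
    n = f.shape[0]
    if rank1 is not None:
        gamma_u, eps, u = rank1
        if gamma_u <= 0:
            raise ValueError("gamma_u must be > 0")
        if eps >= 0:
            x = f + math.sqrt(gamma_u) * np.sqrt(f) * rng.standard_normal((n_draws, n))
            x += math.sqrt(eps) * rng.standard_normal((n_draws, 1)) * np.asarray(u, float)
        else:
            sigma_xi = gamma_u * np.diag(f) + eps * np.outer(u, u)
    if rank1 is None or (rank1 is not None and rank1[1] < 0):
        if sigma_xi is None:
            raise ValueError("provide sigma_xi or a rank1 specification")
        sigma_xi = np.asarray(sigma_xi, dtype=float)
        eigvals, eigvecs = np.linalg.eigh(0.5 * (sigma_xi + sigma_xi.T))
        if eigvals[0] < -1e-10 * max(eigvals[-1], 1.0):
            raise ValueError("sigma_xi must be positive semi-definite")
        factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
        x = f + rng.standard_normal((n_draws, n)) @ factor.T
    if sigma_zeta2 < 0:
        raise ValueError("sigma_zeta2 must be >= 0")
    if sigma_zeta2 > 0:
        x = x + math.sqrt(sigma_zeta2) * rng.standard_normal((n_draws, n))
    return (x >= np.asarray(thresholds, float)[None, :]).astype(float)


def mc_fisher(
    mu_fn: Callable[[float], np.ndarray],
    sample_fn: Callable[[float, int, np.random.Generator], np.ndarray],
    s: float,
    ds: float,
    n_draws: int,
    rng: np.random.Generator,
    n_batches: int = 10,
    ridge: float = 1e-9,
) -> McFisherEstimate:
    """Monte-Carlo linear Fisher information of a (spiking) output layer.

    ``mu'(s)`` is a central finite difference of the analytic mean with step
    ``ds``; the response covariance comes from ``n_draws`` samples at ``s``.
    The estimate is ``mu'^T Cov^-1 mu'`` with a relative diagonal ridge of
    ``ridge * mean(diag)``, evaluated on the sampled support: neurons whose
    observed variance is exactly zero (e.g. spiking cells that never fire
    in ``n_draws`` draws) are excluded, since the Monte-Carlo experiment
    carries no information about them -- without this restriction the ridge
    would convert their analytically nonzero ``mu'`` into arbitrarily large
    spurious information.  The standard error is the spread of the same
    estimator over ``n_batches`` disjoint batches of the draws.
    """
    if ds <= 0:
        raise ValueError("ds must be > 0")
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4 for a stable covariance estimate")
    mu_prime = (np.asarray(mu_fn(s + ds), float) - np.asarray(mu_fn(s - ds), float)) / (
        2.0 * ds
    )
    y = np.asarray(sample_fn(s, n_draws, rng), dtype=float)
    n_silent = int(np.sum(y.var(axis=0) == 0.0))
    if n_silent:
        logger.debug(
            "mc_fisher: %d of %d cells carried no variance in %d draws; "
            "information restricted to the sampled support",
            n_silent, y.shape[1], n_draws,
        )

    def _info(block: np.ndarray) -> float:
        keep = block.var(axis=0) > 0.0
        if not np.any(keep):
            return 0.0
        cov = np.cov(block[:, keep], rowvar=False).reshape(keep.sum(), keep.sum())
        lam = ridge * float(np.mean(np.diag(cov)))
        cov = cov + lam * np.eye(cov.shape[0])
        try:
            return float(mu_prime[keep] @ np.linalg.solve(cov, mu_prime[keep]))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance estimate singular after regularization") from exc

    value = _info(y)
    edges = np.linspace(0, n_draws, n_batches + 1, dtype=int)
    batch_vals = np.array([_info(y[a:b]) for a, b in zip(edges[:-1], edges[1:])])
    se = float(np.std(batch_vals, ddof=1) / math.sqrt(n_batches))
    return McFisherEstimate(value=value, se=se, n_draws=n_draws)
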