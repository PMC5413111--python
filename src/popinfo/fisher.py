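"""Linear Fisher information in the input and output layers.

The linear Fisher information of a population with mean derivative ``f'``
and noise covariance ``Sigma`` is ``I = f'^T Sigma^-1 f'`` -- the inverse
variance of the locally optimal linear stimulus estimator.  The output-layer
information after a feedforward stage with effective weights ``W_eff`` and
effective output noise ``Sigma_eff,eta`` is

    I_y = f'^T [Sigma_xi + (W_eff^T Sigma_eff,eta^-1 W_eff)^-1]^-1 f',

equivalently (for any layer sizes) the information of the propagated signal
``W_eff f'`` against the total output covariance
``W_eff Sigma_xi W_eff^T + Sigma_eff,eta``.

Singular covariances arise legitimately here: pure differential correlations
are rank 1.  When a covariance is singular (or its condition number exceeds
``COND_THRESHOLD``) the information is evaluated through the Moore-Penrose
pseudo-inverse restricted to the support, with a ``PseudoInverseWarning``;
if ``f'`` has a component outside the support the information would be
infinite and an error is raised instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PseudoInverseWarning",
    "InformationProfile",
    "linear_fisher",
    "output_information",
    "output_information_direct",
    "shuffled_information",
    "optimal_output",
    "eigen_information",
    "information_ratio_2d",
    "minimum_information_covariance",
    "total_information",
]

#: relative condition number beyond which the pseudo-inverse path is taken
COND_THRESHOLD = 1e12
PSD_RTOL = 1e-10


class PseudoInverseWarning(UserWarning):
    """A (near-)singular covariance was handled via its pseudo-inverse."""


@dataclass
class InformationProfile:
    """Per-stimulus information values and their grid averages.

    All information values are in radian^-2.  Averages are unweighted means
    over the (equally spaced) stimulus grid.
    """

    stimuli: np.ndarray
    i_x: np.ndarray
    i_y: Optional[np.ndarray] = None
    i_shuffled: Optional[np.ndarray] = None
    i_eta: Optional[np.ndarray] = None

    def mean(self, which: str) -> float:
        vals = getattr(self, which)
        if vals is None:
            raise ValueError(f"profile has no values for {which!r}")
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        cols = {"stimulus": self.stimuli, "I_x": self.i_x}
        for name, attr in (("I_y", "i_y"), ("I_shuffled", "i_shuffled"), ("I_eta", "i_eta")):
            if getattr(self, attr) is not None:
                cols[name] = getattr(self, attr)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _info_psd(f_prime: np.ndarray, sigma: np.ndarray, what: str) -> float:
    """f'^T Sigma^+ f' through a symmetric eigendecomposition."""
    fp = np.asarray(f_prime, dtype=float)
    sigma = 0.5 * (np.asarray(sigma, dtype=float) + np.asarray(sigma, dtype=float).T)
    eigvals, eigvecs = np.linalg.eigh(sigma)
    top = eigvals[-1]
    if eigvals[0] < -PSD_RTOL * max(top, 1.0):
        raise ValueError(
            f"{what} is not positive semi-definite (min eigenvalue {eigvals[0]:.3e})"
        )
    cutoff = top / COND_THRESHOLD if top > 0 else 0.0
    keep = eigvals > cutoff
    if not np.any(keep):
        raise ValueError(f"{what} is numerically zero; information is undefined")
    proj = eigvecs.T @ fp
    if not np.all(keep):
        outside = math.sqrt(float(np.sum(proj[~keep] ** 2)))
        fnorm = np.linalg.norm(fp)
        if outside > 1e-6 * fnorm:
            raise ValueError(
                "signal direction has a component outside the support of a "
                f"singular {what} (|outside| = {outside:.3e}); information "
                "would be infinite"
            )
        warnings.warn(
            f"near-singular {what}: information evaluated on its "
            f"{int(keep.sum())}-dimensional support",
            PseudoInverseWarning,
            stacklevel=3,
        )
    return float(np.sum(proj[keep] ** 2 / eigvals[keep]))


def linear_fisher(f_prime: np.ndarray, sigma: np.ndarray) -> float:
    """Linear Fisher information ``f'^T Sigma^-1 f'`` (pseudo-inverse if singular)."""
    return _info_psd(f_prime, sigma, "covariance")


def output_information(
    f_prime: np.ndarray,
    sigma_xi: np.ndarray,
    w_eff: np.ndarray,
    sigma_eff_eta: np.ndarray,
) -> float:
    """Output-layer information via ``Sigma_y = (W_eff^T Sigma_eff^-1 W_eff)^-1``.

    Requires the inner matrix to be invertible (typically the case when the
    output layer is at least as large as the input layer); otherwise use
    :func:`output_information_direct`.
    """
    fp = np.asarray(f_prime, dtype=float)
    w = np.asarray(w_eff, dtype=float)
    s_eta = np.asarray(sigma_eff_eta, dtype=float)
    inner = w.T @ np.linalg.solve(s_eta, w)
    inner = 0.5 * (inner + inner.T)
    eigvals = np.linalg.eigvalsh(inner)
    if eigvals[0] <= eigvals[-1] / COND_THRESHOLD:
        raise ValueError(
            "W_eff^T Sigma_eff^-1 W_eff is not invertible; use "
            "output_information_direct for under-complete output layers"
        )
    sigma_y = np.linalg.inv(inner)
    return _info_psd(fp, np.asarray(sigma_xi, float) + sigma_y, "total covariance")


def output_information_direct(
    f_prime: np.ndarray,
    sigma_xi: np.ndarray,
    w_eff: np.ndarray,
    sigma_eff_eta: np.ndarray,
) -> float:
    """Output information from the raw output covariance (any layer sizes).

    ``(W_eff f')^T [W_eff Sigma_xi W_eff^T + Sigma_eff,eta]^-1 (W_eff f')``.
    """
    fp = np.asarray(f_prime, dtype=float)
    w = np.asarray(w_eff, dtype=float)
    signal = w @ fp
    total = w @ np.asarray(sigma_xi, float) @ w.T + np.asarray(sigma_eff_eta, float)
    if np.linalg.norm(signal) == 0:
        return 0.0
    return _info_psd(signal, total, "output covariance")


def shuffled_information(f_prime: np.ndarray, sigma_xi: np.ndarray) -> float:
    """Information with inter-neuronal correlations removed (trial shuffling)."""
    d = np.diag(np.asarray(sigma_xi, dtype=float))
    if np.any(d <= 0):
        raise ValueError("trial shuffling requires strictly positive variances")
    fp = np.asarray(f_prime, dtype=float)
    return float(fp @ (fp / d))


def optimal_output(i_x: float, i_eta: float) -> float:
    """Maximum output information ``I_x / (1 + I_x/I_eta)`` given ``I_x``."""
    if i_x < 0 or i_eta <= 0:
        raise ValueError(f"need i_x >= 0 and i_eta > 0, got ({i_x}, {i_eta})")
    return i_x / (1.0 + i_x / i_eta)


def eigen_information(
    f_prime: np.ndarray, eigenvalues: np.ndarray, eigenvectors: np.ndarray
) -> float:
    """Information from an eigen-decomposition: ``|f'|^2 sum_k cos^2(theta_k)/sigma_k^2``.

    ``theta_k`` is the angle between ``f'`` and eigenvector ``k`` (columns of
    ``eigenvectors``); equivalent to ``sum_k (f' . v_k)^2 / sigma_k^2``.
    """
    fp = np.asarray(f_prime, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    v = np.asarray(eigenvectors, dtype=float)
    gram = v.T @ v
    if not np.allclose(gram, np.eye(v.shape[1]), atol=1e-8):
        raise ValueError("eigenvectors must form an orthonormal basis")
    if lam.shape[0] != v.shape[1] or v.shape[0] != v.shape[1]:
        raise ValueError("need a complete eigen-basis (square eigenvector matrix)")
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues must be > 0")
    proj = v.T @ fp
    return float(np.sum(proj**2 / lam))


def information_ratio_2d(
    sigma1: float, sigma2: float, theta: float, sigma_added2: float
) -> float:
    """Two-dimensional information-transmission ratio.

    For a 2-D covariance with principal standard deviations
    ``sigma1 >= sigma2 > 0`` and signal direction at angle ``theta`` from the
    major axis, adding iid noise of variance ``sigma_added2`` scales the
    information by

        [cos^2(theta)/(sigma1^2 + s2) + sin^2(theta)/(sigma2^2 + s2)] /
        [cos^2(theta)/sigma1^2      + sin^2(theta)/sigma2^2]
    """
    if sigma2 <= 0 or sigma1 < sigma2:
        raise ValueError("require sigma1 >= sigma2 > 0 (major axis first)")
    if sigma_added2 < 0:
        raise ValueError("added variance must be >= 0")
    c2, s2 = math.cos(theta) ** 2, math.sin(theta) ** 2
    num = c2 / (sigma1**2 + sigma_added2) + s2 / (sigma2**2 + sigma_added2)
    den = c2 / sigma1**2 + s2 / sigma2**2
    return num / den


def minimum_information_covariance(f_prime: np.ndarray, trace_budget: float):
    """Trace-constrained covariance minimizing the (support-restricted) information.

    Among covariances with ``tr(Sigma) <= C0``, information is minimized by
    concentrating all variance along the signal direction:
    ``Sigma = C0 * f' f'^T / |f'|^2`` with information ``|f'|^2 / C0``.
    Returns ``(Sigma_min, I_min)``.
    """
    fp = np.asarray(f_prime, dtype=float)
    norm2 = float(fp @ fp)
    if norm2 == 0:
        raise ValueError("f_prime must be non-zero")
    if trace_budget <= 0:
        raise ValueError(f"trace budget must be > 0, got {trace_budget}")
    sigma = trace_budget * np.outer(fp, fp) / norm2
    return sigma, norm2 / trace_budget


def total_information(
    var_delta_s: float, info_values: np.ndarray, weights: np.ndarray
) -> float:
    """Total information about the nominal stimulus under stimulus jitter.

    With trial-to-trial jitter of variance ``var_delta_s`` between the
    nominal stimulus and the encoded one, the estimator variance decomposes
    into the jitter variance plus the weighted average of ``1/I(s)``:

        I_tot = 1 / [var_delta_s + sum_s P(s|s0) / I(s)]
    """
    if var_delta_s < 0:
        raise ValueError("jitter variance must be >= 0")
    info = np.asarray(info_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("weights must be non-negative and sum to 1")
    active = w > 0
    if np.any(info[active] <= 0):
        raise ValueError("zero information at a weighted stimulus (infinite variance)")
    return 1.0 / (var_delta_s + float(np.sum(w[active] / info[active])))
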