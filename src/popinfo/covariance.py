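"""Stimulus-dependent noise covariance constructors for the input layer.

The constructions all start from the Poisson-like diagonal base
``Sigma_0 = diag(f(s))`` (variance equal to the mean, Fano factor 1) and add
structure:

* a rank-1 perturbation ``gamma_u * Sigma_0 + eps * u u^T`` whose direction
  ``u(s)`` is either the signal direction ``f'(s)`` itself or a copy of it
  tilted by an angle ``theta_u`` (with ``|u| = |f'|``);
* pure differential correlations ``f' f'^T / I_x`` -- the rank-1, singular
  limit in which all noise lies along the signal direction;
* the alpha-parameterized optimal family interpolating between differential
  correlations (alpha = 0) and the "matched" covariance proportional to the
  effective downstream noise covariance ``Sigma_y`` (alpha = 1).  Every
  positive semi-definite member of the family carries the same input
  information and, after corruption by the downstream noise, the same output
  information.

Two calibration helpers keep the input information fixed while structure is
varied: ``epsilon_match`` solves for the rank-1 strength that makes a tilted
population exactly as informative as a reference, and
``gamma_u_normalization`` computes the overall scale that pins the input
information to a target for any ``(eps_u, u)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Rank1CovarianceSpec",
    "OptimalFamilyMember",
    "poisson_diagonal",
    "tilted_direction",
    "rank1_covariance",
    "rank1_inverse",
    "gamma_u_normalization",
    "normalized_rank1_covariance",
    "epsilon_match",
    "differential_covariance",
    "optimal_family",
    "average_correlation",
    "average_fano",
]

#: relative floor on the minimum eigenvalue used by all PSD checks
PSD_RTOL = 1e-10


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def _check_psd(sigma: np.ndarray, what: str = "covariance") -> np.ndarray:
    """Symmetrize and verify positive semi-definiteness within tolerance."""
    sigma = _symmetrize(np.asarray(sigma, dtype=float))
    eigvals = np.linalg.eigvalsh(sigma)
    scale = max(eigvals[-1], 0.0)
    if eigvals[0] < -PSD_RTOL * max(scale, 1.0):
        raise ValueError(
            f"{what} is not positive semi-definite: "
            f"minimum eigenvalue {eigvals[0]:.6e} (largest {eigvals[-1]:.6e})"
        )
    return sigma


@dataclass(frozen=True)
class Rank1CovarianceSpec:
    """Parameters of a diagonal-plus-rank-1 covariance ``gamma*Sigma_0 + eps*u u^T``."""

    gamma_u: float = 1.0
    epsilon: float = 0.0
    theta_u: float = 0.0


@dataclass(frozen=True)
class OptimalFamilyMember:
    """One member of the family of robustness-optimal input covariances."""

    alpha: float
    input_information: float
    eta_information: float
    sigma_xi: np.ndarray
    sigma_y: np.ndarray


def poisson_diagonal(f_values: np.ndarray) -> np.ndarray:
    """Poisson-like base covariance ``diag(f(s))``.

    All means must be strictly positive: the information formulas divide by
    these variances.
    """
    f = np.asarray(f_values, dtype=float)
    if f.ndim != 1:
        raise ValueError("f_values must be a 1-D vector of mean rates")
    if np.any(f <= 0):
        raise ValueError("all mean responses must be > 0 for a Poisson-like base")
    return np.diag(f)


def tilted_direction(
    f_prime: np.ndarray,
    theta_u: float,
    aux: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Rotate the signal direction by ``theta_u`` while preserving its length.

    The rotation happens in the 2-plane spanned by ``f'`` and the component
    of ``aux`` orthogonal to ``f'``; the result satisfies
    ``angle(u, f') = theta_u`` and ``|u| = |f'|`` exactly.  ``aux`` should be
    one fixed vector per experiment so that ``u(s)`` varies continuously with
    the stimulus; if omitted it is drawn from ``rng``.
    """
    fp = np.asarray(f_prime, dtype=float)
    norm = np.linalg.norm(fp)
    if norm == 0:
        raise ValueError("f_prime must be non-zero")
    fhat = fp / norm
    if theta_u == 0.0:
        return fp.copy()
    if aux is None:
        if rng is None:
            raise ValueError("provide either aux or rng for a nonzero tilt")
        aux = rng.standard_normal(fp.shape[0])
    aux = np.asarray(aux, dtype=float)
    perp = aux - (aux @ fhat) * fhat
    pnorm = np.linalg.norm(perp)
    if pnorm < 1e-12 * np.linalg.norm(aux):
        raise ValueError("aux is (numerically) parallel to f_prime")
    perp /= pnorm
    return norm * (np.cos(theta_u) * fhat + np.sin(theta_u) * perp)


def _rank1_psd_margin(
    sigma0_diag: np.ndarray, gamma_u: float, epsilon: float, u: np.ndarray
) -> float:
    """Determinant-lemma PSD criterion for ``gamma*Sigma_0 + eps*u u^T``.

    The matrix is PSD iff ``gamma > 0`` and ``1 + (eps/gamma) u^T Sigma_0^-1 u >= 0``;
    returns that scalar margin.
    """
    return 1.0 + (epsilon / gamma_u) * float(u @ (u / sigma0_diag))


def rank1_covariance(
    sigma0: np.ndarray, gamma_u: float, epsilon: float, u: np.ndarray
) -> np.ndarray:
    """Build ``Sigma_xi = gamma_u * Sigma_0 + epsilon * u u^T`` (PSD-checked)."""
    sigma0 = np.asarray(sigma0, dtype=float)
    d = np.diag(sigma0).copy()
    if np.any(d <= 0) or np.any(sigma0 - np.diag(d) != 0):
        raise ValueError("sigma0 must be diagonal with positive entries")
    if gamma_u <= 0:
        raise ValueError(f"gamma_u must be > 0, got {gamma_u}")
    u = np.asarray(u, dtype=float)
    sigma = gamma_u * np.diag(d) + epsilon * np.outer(u, u)
    if epsilon < 0 and _rank1_psd_margin(d, gamma_u, epsilon, u) < -PSD_RTOL:
        min_eig = np.linalg.eigvalsh(_symmetrize(sigma))[0]
        raise ValueError(
            "rank-1 perturbation violates positive semi-definiteness: "
            f"minimum eigenvalue {min_eig:.6e} (epsilon={epsilon:.3e})"
        )
    return _symmetrize(sigma)


def rank1_inverse(
    sigma0: np.ndarray, gamma_u: float, epsilon: float, u: np.ndarray
) -> np.ndarray:
    """Sherman-Morrison inverse of ``gamma_u * Sigma_0 + epsilon * u u^T``."""
    sigma0 = np.asarray(sigma0, dtype=float)
    d = np.diag(sigma0)
    if gamma_u <= 0:
        raise ValueError(f"gamma_u must be > 0, got {gamma_u}")
    u = np.asarray(u, dtype=float)
    w = u / d  # Sigma_0^-1 u
    denom = 1.0 + (epsilon / gamma_u) * float(u @ w)
    if abs(denom) < 1e-14:
        raise ValueError("singular configuration: Sherman-Morrison denominator is zero")
    inv = np.diag(1.0 / (gamma_u * d)) - (epsilon / gamma_u**2 / denom) * np.outer(w, w)
    return _symmetrize(inv)


def _rank1_information(
    f_prime: np.ndarray, sigma0_diag: np.ndarray, eps_u: float, u: np.ndarray
) -> float:
    """Input information of ``Sigma_0 + eps_u u u^T`` in closed form."""
    i0 = float(f_prime @ (f_prime / sigma0_diag))
    c = float(f_prime @ (u / sigma0_diag))
    dq = float(u @ (u / sigma0_diag))
    return i0 - eps_u * c * c / (1.0 + eps_u * dq)


def gamma_u_normalization(
    f_prime: np.ndarray,
    sigma0: np.ndarray,
    eps_u: float,
    u: np.ndarray,
    i_x_target: float,
) -> float:
    """Overall scale pinning the input information to ``i_x_target``.

    Returns ``gamma_u = J(eps_u, u) / I_x`` where ``J`` is the information of
    the unscaled perturbed covariance ``Sigma_0 + eps_u u u^T``.  Scaling the
    *whole* perturbed matrix by ``gamma_u`` (see
    :func:`normalized_rank1_covariance`) then yields input information exactly
    equal to the target, for any admissible ``(eps_u, u)``.
    """
    if i_x_target <= 0:
        raise ValueError(f"i_x_target must be > 0, got {i_x_target}")
    d = np.diag(np.asarray(sigma0, dtype=float))
    if np.any(d <= 0):
        raise ValueError("sigma0 must have a strictly positive diagonal")
    gamma = _rank1_information(np.asarray(f_prime, float), d, eps_u, np.asarray(u, float))
    gamma /= i_x_target
    if gamma <= 0:
        raise ValueError(
            f"ill-posed target: normalization gives gamma_u = {gamma:.6e} <= 0"
        )
    return gamma


def normalized_rank1_covariance(
    f_prime: np.ndarray,
    sigma0: np.ndarray,
    eps_u: float,
    u: np.ndarray,
    i_x_target: float,
) -> Tuple[np.ndarray, float]:
    """``Sigma_xi = gamma_u * (Sigma_0 + eps_u u u^T)`` with fixed input information.

    Returns ``(Sigma_xi, gamma_u)``.  This is the construction used to sweep
    the rank-1 strength while holding the input information constant.
    """
    gamma = gamma_u_normalization(f_prime, sigma0, eps_u, u, i_x_target)
    sigma = rank1_covariance(sigma0, gamma, gamma * eps_u, u)
    return sigma, gamma


def epsilon_match(
    f_prime: np.ndarray,
    sigma0: np.ndarray,
    u: np.ndarray,
    i_x_target: float,
) -> float:
    """Solve for the rank-1 strength matching a target input information.

    For ``Sigma_xi = Sigma_0 + eps_u u u^T`` the input information is the
    linear-fractional function ``I0 - eps_u c^2 / (1 + eps_u d)`` with
    ``c = f'^T Sigma_0^-1 u`` and ``d = u^T Sigma_0^-1 u``; the unique
    solution of ``I(eps_u) = I_x_target`` is returned.  Raises if the
    solution does not exist or yields a non-PSD covariance.
    """
    fp = np.asarray(f_prime, dtype=float)
    dg = np.diag(np.asarray(sigma0, dtype=float))
    if np.any(dg <= 0):
        raise ValueError("sigma0 must have a strictly positive diagonal")
    u = np.asarray(u, dtype=float)
    i0 = float(fp @ (fp / dg))
    c = float(fp @ (u / dg))
    dq = float(u @ (u / dg))
    drop = i0 - i_x_target
    denom = c * c - dq * drop
    if abs(denom) < 1e-300 or not np.isfinite(denom):
        raise ValueError("no admissible eps_u: matching equation is singular")
    eps_u = drop / denom
    if 1.0 + eps_u * dq <= 0:
        raise ValueError(
            f"no admissible eps_u: solution {eps_u:.6e} violates positive "
            "semi-definiteness (target information unreachable along u)"
        )
    return eps_u


def differential_covariance(f_prime: np.ndarray, i_x_target: float) -> np.ndarray:
    """Pure differential correlations ``f' f'^T / I_x`` (rank 1, singular)."""
    fp = np.asarray(f_prime, dtype=float)
    if np.linalg.norm(fp) == 0:
        raise ValueError("f_prime must be non-zero")
    if i_x_target <= 0:
        raise ValueError(f"i_x_target must be > 0, got {i_x_target}")
    return np.outer(fp, fp) / i_x_target


def _family_sigma(
    alpha: float, f_prime: np.ndarray, sigma_y: np.ndarray, i_x: float, i_eta: float
) -> np.ndarray:
    return (alpha * i_eta / i_x) * sigma_y + ((1.0 - alpha) / i_x) * np.outer(
        f_prime, f_prime
    )


def optimal_family(
    alpha: float,
    f_prime: np.ndarray,
    sigma_y: np.ndarray,
    i_x_target: float,
) -> OptimalFamilyMember:
    """Member of the robustness-optimal covariance family.

    ``Sigma_xi(alpha) = (alpha * I_eta / I_x) * Sigma_y
    + ((1 - alpha) / I_x) * f' f'^T`` with
    ``I_eta = f'^T Sigma_y^-1 f'``.  ``alpha = 0`` gives pure differential
    correlations; ``alpha = 1`` gives the matched covariance proportional to
    ``Sigma_y``.  Every PSD member has input information ``I_x`` and output
    information ``I_x / (1 + I_x/I_eta)``.

    Raises for non-PSD members, reporting the admissible upper endpoint of
    the ``alpha`` interval found by bisection.
    """
    fp = np.asarray(f_prime, dtype=float)
    if i_x_target <= 0:
        raise ValueError(f"i_x_target must be > 0, got {i_x_target}")
    sigma_y = _check_psd(sigma_y, "sigma_y")
    i_eta = float(fp @ np.linalg.solve(sigma_y, fp))
    sigma = _symmetrize(_family_sigma(alpha, fp, sigma_y, i_x_target, i_eta))
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] < -PSD_RTOL * max(eigvals[-1], 1.0):
        lo, hi = 1.0, alpha  # alpha in [0, 1] is always PSD
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ev = np.linalg.eigvalsh(
                _symmetrize(_family_sigma(mid, fp, sigma_y, i_x_target, i_eta))
            )
            if ev[0] < -PSD_RTOL * max(ev[-1], 1.0):
                hi = mid
            else:
                lo = mid
        raise ValueError(
            f"family member alpha={alpha} is not PSD (min eigenvalue "
            f"{eigvals[0]:.6e}); admissible interval endpoint near alpha={lo:.6f}"
        )
    return OptimalFamilyMember(
        alpha=alpha,
        input_information=i_x_target,
        eta_information=i_eta,
        sigma_xi=sigma,
        sigma_y=sigma_y,
    )


def _as_matrix_list(sigmas):
    if isinstance(sigmas, np.ndarray) and sigmas.ndim == 2:
        return [sigmas.astype(float)]
    return [np.asarray(s, dtype=float) for s in sigmas]


def average_correlation(sigmas) -> float:
    """Mean pairwise correlation over ordered pairs i != j and all matrices."""
    total, count = 0.0, 0
    for s in _as_matrix_list(sigmas):
        d = np.diag(s)
        if np.any(d <= 0):
            raise ValueError("zero or negative variance entry in covariance")
        sd = np.sqrt(d)
        corr = s / np.outer(sd, sd)
        off = ~np.eye(s.shape[0], dtype=bool)
        total += corr[off].sum()
        count += off.sum()
    return total / count


def average_fano(sigmas, f_values) -> float:
    """Mean Fano factor ``Sigma_ii / f_i`` over neurons and all matrices."""
    mats = _as_matrix_list(sigmas)
    fv = np.asarray(f_values, dtype=float)
    fs = [fv] if fv.ndim == 1 else list(fv)
    fanos = []
    for s, f in zip(mats, fs):
        if np.any(f <= 0):
            raise ValueError("all mean responses must be > 0")
        fanos.append(np.diag(s) / f)
    return float(np.mean(fanos))
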