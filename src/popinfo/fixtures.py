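"""Deterministic miniature instances for unit tests and examples."""

from __future__ import annotations

from typing import Any, Dict

import numpy as np

from .channel import dg_thresholds
from .tuning import sample_population

__all__ = ["make_fixture"]


def make_fixture(kind: str, size: int, seed: int) -> Dict[str, Any]:
    """Build a small deterministic test instance.

    Kinds
    -----
    ``population``
        ``size``-neuron Von Mises population with the default parameter
        ranges.
    ``covariance``
        ``size x size`` PSD matrix with its (sorted) eigenvalues reported.
    ``channel``
        identity-weight channel pieces: signal ``f_prime``, diagonal input
        covariance, iid output covariance.
    ``dg``
        a correlated binary-neuron pair (or ``size``-tuple) with means,
        thresholds and the latent Gaussian covariance, suitable for
        orthant-probability checks.
    """
    kinds = {"population": 0, "covariance": 1, "channel": 2, "dg": 3}
    if kind not in kinds:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(kinds[kind],)))
    if kind == "population":
        return {"population": sample_population(size, rng)}
    if kind == "covariance":
        g = rng.standard_normal((size, size))
        sigma = g @ g.T / size + 0.05 * np.eye(size)
        return {"sigma": sigma, "eigenvalues": np.linalg.eigvalsh(sigma)}
    if kind == "channel":
        f_prime = rng.standard_normal(size)
        return {
            "f_prime": f_prime,
            "sigma_xi": np.diag(rng.uniform(0.5, 2.0, size)),
            "weights": np.eye(size),
            "sigma_eta": rng.uniform(0.2, 1.0) * np.eye(size),
        }
    if kind == "dg":
        pop = sample_population(size, rng)
        s = float(rng.uniform(0, 2 * np.pi))
        f = pop.rates(s)
        rho = rng.uniform(-0.5, 0.5)
        sd = np.sqrt(f)
        sigma = np.outer(sd, sd) * (rho + (1 - rho) * np.eye(size))
        return {
            "f": f,
            "sigma_xi": sigma,
            "thresholds": dg_thresholds(pop.baseline, pop.amplitude),
            "latent_correlation": rho,
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
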