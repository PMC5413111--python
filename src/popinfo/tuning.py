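"""Heterogeneous Von Mises tuning-curve populations.

A population of ``n`` neurons encodes a circular stimulus ``s`` (radians on
``[0, 2*pi)``) through mean firing rates

    f_i(s) = rho_i + upsilon_i * exp(beta_i * (cos(s - phi_i) - 1)),

the Von Mises tuning curve with baseline ``rho_i``, amplitude ``upsilon_i``,
width parameter ``beta_i`` and preferred stimulus ``phi_i``.  The stimulus
derivative ``f'(s)`` (the "signal direction" of the population) is available
in closed form and is the quantity that enters every information formula, so
it is computed analytically; finite differences are used only as a test
oracle.

Populations are sampled from per-parameter uniform distributions.  The
default ranges are upsilon in [1, 51], beta in [1, 6], phi in [0, 2*pi) and
rho in [0, 1], which produce firing rates and tuning widths typical of
orientation/direction-selective sensory neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VonMisesParams",
    "TuningPopulation",
    "PAPER_RANGES",
    "vonmises_curve",
    "vonmises_derivative",
    "sample_population",
]

#: Default uniform sampling ranges for (rho, upsilon, beta, phi).
PAPER_RANGES: Mapping[str, Tuple[float, float]] = {
    "rho": (0.0, 1.0),
    "upsilon": (1.0, 51.0),
    "beta": (1.0, 6.0),
    "phi": (0.0, 2.0 * math.pi),
}

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class VonMisesParams:
    """Parameters of one Von Mises tuning curve.

    Attributes
    ----------
    baseline : float
        Offset rate ``rho`` (>= 0).
    amplitude : float
        Peak modulation ``upsilon`` (> 0); the peak rate is
        ``baseline + amplitude``.
    width : float
        Concentration ``beta`` (> 0); larger values give narrower tuning.
    preferred : float
        Preferred stimulus ``phi`` in radians, wrapped to ``[0, 2*pi)``.
    """

    baseline: float
    amplitude: float
    width: float
    preferred: float

    def __post_init__(self) -> None:
        vals = (self.baseline, self.amplitude, self.width, self.preferred)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"Von Mises parameters must be finite, got {vals}")
        if self.baseline < 0:
            raise ValueError(f"baseline rho must be >= 0, got {self.baseline}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude upsilon must be > 0, got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"width beta must be > 0, got {self.width}")
        object.__setattr__(self, "preferred", self.preferred % TWO_PI)


def vonmises_curve(params: VonMisesParams, s: float) -> float:
    """Mean firing rate ``rho + upsilon * exp(beta * (cos(s - phi) - 1))``."""
    if not math.isfinite(s):
        raise ValueError(f"stimulus must be finite, got {s}")
    d = s - params.preferred
    return params.baseline + params.amplitude * math.exp(
        params.width * (math.cos(d) - 1.0)
    )


def vonmises_derivative(params: VonMisesParams, s: float) -> float:
    """Analytic derivative ``df/ds = -upsilon * beta * sin(s - phi) * exp(...)``."""
    if not math.isfinite(s):
        raise ValueError(f"stimulus must be finite, got {s}")
    d = s - params.preferred
    return (
        -params.amplitude
        * params.width
        * math.sin(d)
        * math.exp(params.width * (math.cos(d) - 1.0))
    )


class TuningPopulation:
    """A fixed set of Von Mises tuning curves with vectorized evaluation.

    Parameters are held as flat arrays (one entry per neuron); ``rates`` and
    ``derivatives`` return the ``n``-vectors ``f(s)`` and ``f'(s)`` for a
    scalar stimulus.
    """

    def __init__(
        self,
        baseline: np.ndarray,
        amplitude: np.ndarray,
        width: np.ndarray,
        preferred: np.ndarray,
    ) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (baseline, amplitude, width, preferred)]
        n = arrs[0].shape[0]
        if any(a.ndim != 1 or a.shape[0] != n for a in arrs):
            raise ValueError("parameter arrays must be 1-D with equal length")
        if n < 1:
            raise ValueError("population must contain at least one neuron")
        # route validation through VonMisesParams so scalar and vector paths agree
        for row in zip(*arrs):
            VonMisesParams(*row)
        self.baseline, self.amplitude, self.width, self.preferred = arrs
        self.preferred = self.preferred % TWO_PI

    @property
    def n(self) -> int:
        return self.baseline.shape[0]

    def __len__(self) -> int:
        return self.n

    def params(self, i: int) -> VonMisesParams:
        return VonMisesParams(
            self.baseline[i], self.amplitude[i], self.width[i], self.preferred[i]
        )

    def rates(self, s: float) -> np.ndarray:
        """``f(s)``: mean rates of all neurons at stimulus ``s``."""
        if not math.isfinite(s):
            raise ValueError(f"stimulus must be finite, got {s}")
        d = s - self.preferred
        return self.baseline + self.amplitude * np.exp(self.width * (np.cos(d) - 1.0))

    def derivatives(self, s: float) -> np.ndarray:
        """``f'(s)``: stimulus derivatives of all mean rates at ``s``."""
        if not math.isfinite(s):
            raise ValueError(f"stimulus must be finite, got {s}")
        d = s - self.preferred
        return -self.amplitude * self.width * np.sin(d) * np.exp(
            self.width * (np.cos(d) - 1.0)
        )

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": np.arange(self.n),
                "rho": self.baseline,
                "upsilon": self.amplitude,
                "beta": self.width,
                "phi": self.preferred,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TuningPopulation":
        df = df.sort_values("neuron_id")
        return cls(
            df["rho"].to_numpy(),
            df["upsilon"].to_numpy(),
            df["beta"].to_numpy(),
            df["phi"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "TuningPopulation":
        return cls.from_frame(pd.read_csv(path))


def _validate_ranges(ranges: Mapping[str, Tuple[float, float]]) -> None:
    for name in ("rho", "upsilon", "beta", "phi"):
        if name not in ranges:
            raise ValueError(f"missing sampling range for {name!r}")
        lo, hi = ranges[name]
        if not (math.isfinite(lo) and math.isfinite(hi)) or not lo < hi:
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")


def sample_population(
    n: int,
    rng: np.random.Generator,
    ranges: Mapping[str, Tuple[float, float]] = PAPER_RANGES,
) -> TuningPopulation:
    """Draw ``n`` tuning curves with iid uniform parameters.

    Each parameter of each neuron is drawn independently and uniformly from
    its configured half-open interval.  The generator ``rng`` is the only
    source of randomness, so populations are reproducible given a seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _validate_ranges(ranges)
    draws = {k: rng.uniform(*ranges[k], size=n) for k in ("rho", "upsilon", "beta", "phi")}
    return TuningPopulation(draws["rho"], draws["upsilon"], draws["beta"], draws["phi"])
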