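"""Deterministic vector field of a two-oscillator motif of coupled λ–ω units.

Each unit is the Hopf normal form written in rectangular coordinates
(x, y), with amplitude r = sqrt(x² + y²).  The radial growth rate

    λ(r) = λ₀ + α r² + γ r⁴

controls whether the amplitude grows or decays, and the angular frequency

    ω(r) = ω₀ + ω₁ r²

sets the rotation rate.  With α < 0 and γ < 0 the unit sits near a
supercritical Hopf bifurcation at λ₀ = 0: for λ₀ < 0 the origin is the
only attractor (excitable/quiescent regime), for λ₀ > 0 a stable limit
cycle of radius r* with λ(r*) = 0 surrounds the unstable origin.

The two units interact through diffusive coupling d_i (x_j − x_i),
d_i (y_j − y_i): the strength d_i scales the input *into* oscillator i,
so d₁ ≠ d₂ is uneven (asymmetric) coupling.  Diffusive coupling vanishes
identically on the synchrony manifold (x₁, y₁) = (x₂, y₂).

State is kept rectangular rather than polar because the stochastic
forcing used elsewhere in this package is additive in x only; polar
conversion is done on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

#: default exploration range for the excitatory coupling strengths
COUPLING_RANGE = (0.01, 0.3)


class UnsupportedRegimeError(ValueError):
    """An operation requires the supercritical configuration (α < 0, γ < 0)."""


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one λ–ω oscillator.

    Parameters
    ----------
    lambda0 : float
        Hopf control parameter (dimensionless).  Negative values put the
        unit in the excitable regime; the default −0.5 is the standard
        excitable operating point used throughout this package.
    alpha, gamma : float
        Quadratic and quartic coefficients of the radial growth rate
        λ(r).  Both negative for the supercritical case.
    omega0 : float
        Base angular frequency (rad per time unit).
    omega1 : float
        Amplitude–frequency coefficient; 0 means amplitude-independent
        rotation (isochronous oscillator).
    """

    lambda0: float = -0.5
    alpha: float = -0.2
    gamma: float = -0.2
    omega0: float = 2.0
    omega1: float = 0.0

    def with_lambda0(self, lambda0: float) -> "OscillatorParams":
        """Copy of these parameters at a different control-parameter value."""
        return replace(self, lambda0=float(lambda0))


@dataclass(frozen=True)
class CouplingParams:
    """Diffusive coupling strengths; ``d1`` scales input into oscillator 1.

    Values outside the default exploration range [0.01, 0.3] are allowed
    but logged, since the dynamics there are not part of the standard
    operating envelope of this model.
    """

    d1: float = 0.3
    d2: float = 0.01

    def __post_init__(self) -> None:
        for name, d in (("d1", self.d1), ("d2", self.d2)):
            if d < 0:
                raise ValueError(f"coupling strength {name} must be nonnegative, got {d}")
            if d != 0.0 and not (COUPLING_RANGE[0] <= d <= COUPLING_RANGE[1]):
                logger.warning(
                    "coupling strength %s=%g outside the standard range [%g, %g]",
                    name, d, *COUPLING_RANGE,
                )


@dataclass(frozen=True)
class MotifState:
    """Rectangular state of the two-oscillator motif."""

    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def r1(self) -> float:
        return float(np.hypot(self.x1, self.y1))

    @property
    def r2(self) -> float:
        return float(np.hypot(self.x2, self.y2))

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    @classmethod
    def from_array(cls, a) -> "MotifState":
        x1, y1, x2, y2 = np.asarray(a, dtype=float)
        return cls(float(x1), float(y1), float(x2), float(y2))


def lambda_amp(r, p: OscillatorParams):
    """Radial growth rate λ(r) = λ₀ + α r² + γ r⁴.

    Accepts a scalar or array of nonnegative amplitudes.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("amplitude r must be nonnegative")
    r2 = r * r
    out = p.lambda0 + p.alpha * r2 + p.gamma * r2 * r2
    return float(out) if out.ndim == 0 else out


def omega_freq(r, p: OscillatorParams):
    """Angular frequency ω(r) = ω₀ + ω₁ r² (rad per time unit)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("amplitude r must be nonnegative")
    out = p.omega0 + p.omega1 * r * r
    return float(out) if out.ndim == 0 else out


def drift(state, p: OscillatorParams, c: CouplingParams) -> np.ndarray:
    """Deterministic right-hand side for (x₁, y₁, x₂, y₂).

    dx_i = λ(r_i) x_i − ω(r_i) y_i + d_i (x_j − x_i)
    dy_i = ω(r_i) x_i + λ(r_i) y_i + d_i (y_j − y_i)
    """
    if isinstance(state, MotifState):
        x1, y1, x2, y2 = state.x1, state.y1, state.x2, state.y2
    else:
        x1, y1, x2, y2 = (float(v) for v in np.asarray(state, dtype=float))
    r1s = x1 * x1 + y1 * y1
    r2s = x2 * x2 + y2 * y2
    l1 = p.lambda0 + p.alpha * r1s + p.gamma * r1s * r1s
    l2 = p.lambda0 + p.alpha * r2s + p.gamma * r2s * r2s
    w1 = p.omega0 + p.omega1 * r1s
    w2 = p.omega0 + p.omega1 * r2s
    return np.array(
        [
            l1 * x1 - w1 * y1 + c.d1 * (x2 - x1),
            w1 * x1 + l1 * y1 + c.d1 * (y2 - y1),
            l2 * x2 - w2 * y2 + c.d2 * (x1 - x2),
            w2 * x2 + l2 * y2 + c.d2 * (y1 - y2),
        ]
    )


def limit_cycle_radius(p: OscillatorParams):
    """Radius of the stable limit cycle of a single uncoupled oscillator.

    Solves λ₀ + α r² + γ r⁴ = 0 for the positive root.  In the
    supercritical configuration (α < 0, γ < 0) exactly one positive root
    in r² exists for λ₀ > 0; for λ₀ ≤ 0 there is no stable cycle and
    ``None`` is returned.

    Raises
    ------
    UnsupportedRegimeError
        If α ≥ 0 or γ ≥ 0 (not the supercritical case this package
        models).
    """
    if p.alpha >= 0 or p.gamma >= 0:
        raise UnsupportedRegimeError(
            f"limit_cycle_radius requires alpha < 0 and gamma < 0, "
            f"got alpha={p.alpha}, gamma={p.gamma}"
        )
    if p.lambda0 <= 0:
        return None
    # quadratic in u = r²:  γ u² + α u + λ₀ = 0
    disc = p.alpha * p.alpha - 4.0 * p.gamma * p.lambda0
    s = np.sqrt(disc)
    roots = [(-p.alpha + s) / (2.0 * p.gamma), (-p.alpha - s) / (2.0 * p.gamma)]
    pos = [u for u in roots if u > 0]
    if len(pos) != 1:
        raise UnsupportedRegimeError(
            f"expected exactly one positive r² root of the radial polynomial, got {pos}"
        )
    return float(np.sqrt(pos[0]))
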