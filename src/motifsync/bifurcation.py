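"""Linear stability of the origin and Hopf loci of the coupled motif.

At the origin the Jacobian of the deterministic motif decomposes into
the single-unit rotation block λ₀ I + ω₀ J (J the 2×2 symplectic
rotation generator) plus the diffusive coupling matrix
K = [[−d₁, d₁], [d₂, −d₂]] acting across units.  K has eigenvalues 0
and −(d₁ + d₂) and commutes blockwise with the rotation part, so the
4×4 spectrum is exactly

    { λ₀ ± i ω₀,  λ₀ − (d₁ + d₂) ± i ω₀ }.

Two Hopf points follow: HB₁ where λ₀ crosses 0 (independent of the
coupling) and HB₂ where λ₀ = d₁ + d₂.  Both are available in closed
form and by bracketed root-finding on the numerically computed
eigenvalues; the two routes must agree to 1e−8.

Axis conventions.  Two-parameter loci are stored as λ₀ as a function of
the coupling value on the grid, i.e. the fitted slope is dλ₀/dd.  The
conventional presentation of such diagrams puts the coupling strength on
the vertical axis, in which frame the displayed slope is the reciprocal:
a symmetric-coupling locus λ₀ = 2d (dλ₀/dd = 2) displays with slope 1/2.
``HBLocus.figure_frame_slope`` performs that conversion explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import CouplingParams, OscillatorParams

#: allowed range for locus coupling grids
LOCUS_GRID_RANGE = (0.0, 0.5)


class BracketingError(RuntimeError):
    """Numeric Hopf detection could not bracket a sign change."""


@dataclass(frozen=True)
class HopfPoints:
    """The two Hopf bifurcation points of the coupled motif."""

    hb1_lambda0: float
    hb2_lambda0: float
    method: str  # "closed_form" | "numeric"


@dataclass(frozen=True)
class HBLocus:
    """One-parameter family of HB₂ points over a coupling grid, with a linear fit."""

    mode: str  # "symmetric" | "vary_d1_fixed_d2" | "vary_d2_fixed_d1"
    fixed_value: float | None
    parameter_axis: np.ndarray  # coupling grid
    lambda0_values: np.ndarray  # HB₂ locus, λ₀(d)
    hb1_values: np.ndarray
    fitted_slope: float  # dλ₀/dd
    fitted_intercept: float
    residuals: np.ndarray
    method: str = "closed_form"
    d1_values: np.ndarray = field(default=None, repr=False)
    d2_values: np.ndarray = field(default=None, repr=False)

    @property
    def figure_frame_slope(self) -> float:
        """Slope with the coupling on the vertical axis (dd/dλ₀)."""
        if self.fitted_slope == 0:
            raise ZeroDivisionError("locus is flat in lambda0; frame slope undefined")
        return 1.0 / self.fitted_slope


def origin_jacobian(p: OscillatorParams, c: CouplingParams, lambda0: float) -> np.ndarray:
    """4×4 Jacobian of the deterministic motif at the origin (noise off)."""
    w = p.omega0  # ω₁ terms vanish at r = 0
    return np.array(
        [
            [lambda0 - c.d1, -w, c.d1, 0.0],
            [w, lambda0 - c.d1, 0.0, c.d1],
            [c.d2, 0.0, lambda0 - c.d2, -w],
            [0.0, c.d2, w, lambda0 - c.d2],
        ]
    )


def origin_eigenvalues(p: OscillatorParams, c: CouplingParams, lambda0: float) -> np.ndarray:
    """Eigenvalues of the origin Jacobian, sorted by descending real part.

    Equals {λ₀ ± iω₀, λ₀ − (d₁+d₂) ± iω₀}; computed numerically so the
    closed form can be cross-checked against it.
    """
    ev = np.linalg.eigvals(origin_jacobian(p, c, lambda0))
    return ev[np.argsort(-ev.real, kind="stable")]


def hopf_points(
    p: OscillatorParams, c: CouplingParams, method: str = "closed_form"
) -> HopfPoints:
    """Locate HB₁ and HB₂ in λ₀ for fixed coupling.

    closed_form: HB₁ = 0, HB₂ = d₁ + d₂ (exact, from the origin
    spectrum).  numeric: bracketed root-finding on the maximal and
    minimal eigenvalue real parts over λ₀ ∈ [−0.1, d₁+d₂+0.1].
    """
    if c.d1 < 0 or c.d2 < 0:
        raise ValueError("coupling strengths must be nonnegative")
    dsum = c.d1 + c.d2
    if method == "closed_form":
        return HopfPoints(0.0, dsum, "closed_form")
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    def re_max(lam: float) -> float:
        return origin_eigenvalues(p, c, lam).real.max()

    def re_min(lam: float) -> float:
        return origin_eigenvalues(p, c, lam).real.min()

    lo, hi = -0.1, dsum + 0.1
    for f in (re_max, re_min):
        if f(lo) * f(hi) > 0:
            raise BracketingError(
                f"no sign change of eigenvalue real part over lambda0 in [{lo}, {hi}]"
            )
    hb1 = brentq(re_max, lo, hi, xtol=1e-12)
    hb2 = brentq(re_min, lo, hi, xtol=1e-12)
    return HopfPoints(float(hb1), float(hb2), "numeric")


def hb2_locus(
    p: OscillatorParams,
    mode: str,
    grid,
    fixed_value: float = 0.0,
    method: str = "closed_form",
) -> HBLocus:
    """Trace the HB₂ locus over a coupling grid and fit a straight line.

    Modes: ``symmetric`` (d₁ = d₂ = grid value), ``vary_d1_fixed_d2``
    and ``vary_d2_fixed_d1`` (fixed side at ``fixed_value``).  Slope and
    intercept are a least-squares fit of λ₀ against the grid; residuals
    are reported alongside.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("locus grid must contain at least 3 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("locus grid must be strictly increasing")
    if grid.min() < LOCUS_GRID_RANGE[0] or grid.max() > LOCUS_GRID_RANGE[1]:
        raise ValueError(f"locus grid must lie within {LOCUS_GRID_RANGE}")
    if mode not in ("symmetric", "vary_d1_fixed_d2", "vary_d2_fixed_d1"):
        raise ValueError(f"unknown locus mode {mode!r}")
    if mode != "symmetric" and fixed_value < 0:
        raise ValueError("fixed_value must be nonnegative")

    d1s, d2s = [], []
    for d in grid:
        if mode == "symmetric":
            d1, d2 = d, d
        elif mode == "vary_d1_fixed_d2":
            d1, d2 = d, fixed_value
        else:
            d1, d2 = fixed_value, d
        d1s.append(d1)
        d2s.append(d2)
    hps = [hopf_points(p, CouplingParams(d1, d2), method) for d1, d2 in zip(d1s, d2s)]
    lam = np.array([hp.hb2_lambda0 for hp in hps])
    hb1 = np.array([hp.hb1_lambda0 for hp in hps])
    slope, intercept = np.polyfit(grid, lam, 1)
    resid = lam - (slope * grid + intercept)
    return HBLocus(
        mode=mode,
        fixed_value=None if mode == "symmetric" else float(fixed_value),
        parameter_axis=grid,
        lambda0_values=lam,
        hb1_values=hb1,
        fitted_slope=float(slope),
        fitted_intercept=float(intercept),
        residuals=resid,
        method=method,
        d1_values=np.array(d1s),
        d2_values=np.array(d2s),
    )


def write_loci_csv(loci, path) -> None:
    """Write one or more loci as tidy CSV rows (mode, d1, d2, hb1, hb2, method)."""
    if isinstance(loci, HBLocus):
        loci = [loci]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mode", "d1", "d2", "hb1_lambda0", "hb2_lambda0", "method"])
        for locus in loci:
            for d1, d2, hb1, hb2 in zip(
                locus.d1_values, locus.d2_values, locus.hb1_values, locus.lambda0_values
            ):
                # shortest round-trip float representation
                w.writerow(
                    [locus.mode, repr(float(d1)), repr(float(d2)), repr(float(hb1)),
                     repr(float(hb2)), locus.method]
                )
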