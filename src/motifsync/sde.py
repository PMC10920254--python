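"""Stochastic integration of the two-oscillator motif.

The motif is driven by independent additive white noise on the x
coordinate of each unit only:

    dx_i = [λ(r_i) x_i − ω(r_i) y_i + d_i (x_j − x_i)] dt + δ_i dη_i
    dy_i = [ω(r_i) x_i + λ(r_i) y_i + d_i (y_j − y_i)] dt

with η_i independent standard Wiener processes and δ_i the per-unit
noise intensities (asymmetric noise when δ₁ ≠ δ₂).  Integration is
Euler–Maruyama with fixed step dt; the noise being additive, the scheme
is strong order 1 and no higher-order correction is warranted.

Reproducibility contract.  Each trial k of an ensemble draws from its
own substream, derived deterministically from (seed, substream prefix,
k) via ``numpy.random.SeedSequence`` spawn keys.  Within a trial the
draw order is fixed: four initial-condition normals (x₁, y₁, x₂, y₂),
then per step one increment for x₁ followed by one for x₂.  The batched
ensemble path performs the identical scalar arithmetic per trial, so
``ensemble(...)[k]`` is bit-identical to ``simulate(...,
trial_index=k)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
import json
import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .model import CouplingParams, OscillatorParams, drift

logger = logging.getLogger(__name__)

#: default exploration range for noise intensities (δ = 0 is the deterministic limit)
NOISE_RANGE = (0.01, 5.0)


class IntegrationBlowUpError(RuntimeError):
    """State became non-finite during integration."""


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise intensities applied to x₁ and x₂ respectively."""

    delta1: float = 0.0
    delta2: float = 0.0

    def __post_init__(self) -> None:
        for name, d in (("delta1", self.delta1), ("delta2", self.delta2)):
            if d < 0:
                raise ValueError(f"noise intensity {name} must be nonnegative, got {d}")
            if d != 0.0 and not (NOISE_RANGE[0] <= d <= NOISE_RANGE[1]):
                logger.warning(
                    "noise intensity %s=%g outside the standard range [%g, %g]",
                    name, d, *NOISE_RANGE,
                )


@dataclass(frozen=True)
class SimSettings:
    """Integration settings.

    dt=0.01 is the production step; t_transient is the initial stretch
    discarded before any phase statistics; initial conditions are drawn
    i.i.d. N(0, ic_sd²) per coordinate.
    """

    dt: float = 0.01
    t_end: float = 500.0
    t_transient: float = 100.0
    n_trials: int = 200
    seed: int = 0
    ic_sd: float = 0.008

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if not (0 <= self.t_transient < self.t_end):
            raise ValueError(
                f"t_transient must satisfy 0 <= t_transient < t_end, "
                f"got {self.t_transient} vs t_end={self.t_end}"
            )
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")
        if self.ic_sd < 0:
            raise ValueError(f"ic_sd must be nonnegative, got {self.ic_sd}")
        if self.seed < 0:
            raise ValueError(f"seed must be a nonnegative integer, got {self.seed}")
        if self.dt > 0.01:
            logger.warning("dt=%g exceeds the production step 0.01", self.dt)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def replace(self, **kw) -> "SimSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class Trajectory:
    """Sampled time series of the motif with full provenance."""

    times: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x2: np.ndarray
    y2: np.ndarray
    config: dict = field(repr=False)
    seed: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("x1", "y1", "x2", "y2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length != times length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def xy(self, i: int):
        """(x_i, y_i) series for oscillator i in {1, 2}."""
        if i == 1:
            return self.x1, self.y1
        if i == 2:
            return self.x2, self.y2
        raise ValueError("oscillator index must be 1 or 2")

    def terminal_state(self) -> np.ndarray:
        return np.array([self.x1[-1], self.y1[-1], self.x2[-1], self.y2[-1]])


@njit(cache=True)
def _em_core(ic, z, dt, sqdt, lam0, al, ga, om0, om1, d1, d2, de1, de2):  # pragma: no cover
    m = ic.shape[0]
    n = z.shape[1]
    out = np.empty((m, n + 1, 4))
    bad = np.full(m, -1, dtype=np.int64)
    for t in range(m):
        x1 = ic[t, 0]
        y1 = ic[t, 1]
        x2 = ic[t, 2]
        y2 = ic[t, 3]
        out[t, 0, 0] = x1
        out[t, 0, 1] = y1
        out[t, 0, 2] = x2
        out[t, 0, 3] = y2
        for k in range(n):
            r1s = x1 * x1 + y1 * y1
            r2s = x2 * x2 + y2 * y2
            l1 = lam0 + al * r1s + ga * r1s * r1s
            l2 = lam0 + al * r2s + ga * r2s * r2s
            w1 = om0 + om1 * r1s
            w2 = om0 + om1 * r2s
            nx1 = x1 + dt * (l1 * x1 - w1 * y1 + d1 * (x2 - x1)) + de1 * sqdt * z[t, k, 0]
            ny1 = y1 + dt * (w1 * x1 + l1 * y1 + d1 * (y2 - y1))
            nx2 = x2 + dt * (l2 * x2 - w2 * y2 + d2 * (x1 - x2)) + de2 * sqdt * z[t, k, 1]
            ny2 = y2 + dt * (w2 * x2 + l2 * y2 + d2 * (y1 - y2))
            x1, y1, x2, y2 = nx1, ny1, nx2, ny2
            out[t, k + 1, 0] = x1
            out[t, k + 1, 1] = y1
            out[t, k + 1, 2] = x2
            out[t, k + 1, 3] = y2
            if not (
                np.isfinite(x1) and np.isfinite(y1) and np.isfinite(x2) and np.isfinite(y2)
            ):
                bad[t] = k + 1
                break
    return out, bad


def _trial_rng(seed: int, substream: tuple, trial_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(*substream, trial_index))
    )


def _config_snapshot(p, c, n, s) -> dict:
    return {
        "oscillator": asdict(p),
        "coupling": asdict(c),
        "noise": asdict(n),
        "simulation": asdict(s),
    }


def _draw_trial(rng: np.random.Generator, s: SimSettings):
    ic = rng.normal(0.0, s.ic_sd, 4)
    z = rng.standard_normal((s.n_steps, 2))
    return ic, z


def _run_batch(ic, z, p, c, n, s):
    out, bad = _em_core(
        ic, z, s.dt, np.sqrt(s.dt),
        p.lambda0, p.alpha, p.gamma, p.omega0, p.omega1,
        c.d1, c.d2, n.delta1, n.delta2,
    )
    for t in range(len(bad)):
        if bad[t] >= 0:
            raise IntegrationBlowUpError(
                f"non-finite state at step {int(bad[t])} (t={bad[t] * s.dt:g}) in trial {t}"
            )
    return out


def simulate(
    p: OscillatorParams,
    c: CouplingParams,
    n: NoiseParams,
    s: SimSettings,
    trial_index: int = 0,
    substream: tuple = (),
    ic=None,
) -> Trajectory:
    """Integrate one seeded trial by Euler–Maruyama.

    ``ic`` overrides the random initial condition (useful for
    deterministic cross-checks); the noise stream is unaffected by the
    override.
    """
    rng = _trial_rng(s.seed, substream, trial_index)
    ic_drawn, z = _draw_trial(rng, s)
    if ic is not None:
        ic_drawn = np.asarray(ic, dtype=float)
        if ic_drawn.shape != (4,):
            raise ValueError("ic must have shape (4,)")
    out = _run_batch(ic_drawn[None, :], z[None, :, :], p, c, n, s)
    times = np.arange(s.n_steps + 1) * s.dt
    return Trajectory(
        times=times,
        x1=out[0, :, 0], y1=out[0, :, 1], x2=out[0, :, 2], y2=out[0, :, 3],
        config=_config_snapshot(p, c, n, s),
        seed=s.seed,
        trial_index=trial_index,
    )


def ensemble(
    p: OscillatorParams,
    c: CouplingParams,
    n: NoiseParams,
    s: SimSettings,
    substream: tuple = (),
) -> list[Trajectory]:
    """Integrate ``s.n_trials`` independent trials.

    Trial k uses the substream (seed, *substream, k); results are
    reproducible trial-by-trial and identical to calling ``simulate``
    with ``trial_index=k``.
    """
    ics = np.empty((s.n_trials, 4))
    zs = np.empty((s.n_trials, s.n_steps, 2))
    for k in range(s.n_trials):
        ic, z = _draw_trial(_trial_rng(s.seed, substream, k), s)
        ics[k] = ic
        zs[k] = z
    out = _run_batch(ics, zs, p, c, n, s)
    times = np.arange(s.n_steps + 1) * s.dt
    cfg = _config_snapshot(p, c, n, s)
    return [
        Trajectory(
            times=times,
            x1=out[k, :, 0], y1=out[k, :, 1], x2=out[k, :, 2], y2=out[k, :, 3],
            config=cfg,
            seed=s.seed,
            trial_index=k,
        )
        for k in range(s.n_trials)
    ]


def integrate_deterministic(
    p: OscillatorParams, c: CouplingParams, state0, s: SimSettings
) -> Trajectory:
    """High-accuracy deterministic integration (noise-free oracle).

    Adaptive Runge–Kutta (RK45, rtol 1e−10) of the drift, sampled on the
    same grid as the Euler–Maruyama output; serves as the convergence
    reference for the δ = 0 limit.
    """
    state0 = np.asarray(state0, dtype=float)
    times = np.arange(s.n_steps + 1) * s.dt
    sol = solve_ivp(
        lambda _, y: drift(y, p, c),
        (0.0, float(times[-1])),
        state0,
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
        method="RK45",
    )
    if not sol.success:
        raise IntegrationBlowUpError(f"deterministic integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise IntegrationBlowUpError("non-finite state in deterministic integration")
    return Trajectory(
        times=times,
        x1=y[0], y1=y[1], x2=y[2], y2=y[3],
        config=_config_snapshot(p, c, NoiseParams(0.0, 0.0), s),
        seed=s.seed,
        trial_index=0,
    )


def write_trajectory(traj: Trajectory, prefix: str) -> None:
    """Write a trajectory as ``<prefix>.csv`` plus a ``<prefix>.json`` sidecar."""
    df = pd.DataFrame(
        {"t": traj.times, "x1": traj.x1, "y1": traj.y1, "x2": traj.x2, "y2": traj.y2}
    )
    df.to_csv(f"{prefix}.csv", index=False, float_format="%.17g")
    sidecar = {"config": traj.config, "seed": traj.seed, "trial_index": traj.trial_index}
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_trajectory(prefix: str) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    df = pd.read_csv(f"{prefix}.csv")
    with open(f"{prefix}.json") as fh:
        sidecar = json.load(fh)
    return Trajectory(
        times=df["t"].to_numpy(),
        x1=df["x1"].to_numpy(), y1=df["y1"].to_numpy(),
        x2=df["x2"].to_numpy(), y2=df["y2"].to_numpy(),
        config=sidecar["config"],
        seed=sidecar["seed"],
        trial_index=sidecar["trial_index"],
    )
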