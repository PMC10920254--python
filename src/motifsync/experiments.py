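"""Experiment drivers: parameter sweeps over noise and coupling.

Each driver is a pure function of (parameters, settings, seed): trial k
of grid cell (i, j) draws from the substream (seed, i, j, k), so any
single cell can be regenerated in isolation and re-running an
experiment reproduces it bit-for-bit.

Grid conventions.  Noise-intensity axes are logarithmically spaced over
[0.01, 5] by default — the interesting structure (both synchrony optima)
spans two decades — while coupling axes are linear over [0.01, 0.3].
Heat-map minima are located twice: the absolute minimum is the raw grid
argmin (ties broken toward smaller δ₁+δ₂, then smaller δ₁), and local
minima are cells strictly below their 4-neighbors after a 3×3 mean
smoothing pass that suppresses Monte-Carlo speckle.

Trial budget tiers: ``paper`` (N=200 trials, horizon 500), ``standard``
(N=50) and ``smoke`` (N=8, short horizon) trade statistical precision
for runtime; every result records which settings produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .measures import (
    HistogramSpec,
    SyncSummary,
    UndefinedBetaError,
    mean_abs_phase_diff,
    mean_phase_coherence,
    snr_beta,
    sync_index_rho,
    trial_summary,
)
from .model import CouplingParams, OscillatorParams
from .phase_filter import FilterSpec, PhaseSeries, extract_phases, lowpass
from .sde import NoiseParams, SimSettings, ensemble


@dataclass(frozen=True)
class Tier:
    n_trials: int
    t_end: float
    t_transient: float


TIERS = {
    "paper": Tier(n_trials=200, t_end=500.0, t_transient=100.0),
    "standard": Tier(n_trials=50, t_end=500.0, t_transient=100.0),
    "smoke": Tier(n_trials=8, t_end=120.0, t_transient=20.0),
}


def settings_for_tier(tier: str, seed: int = 0, dt: float = 0.01, **overrides) -> SimSettings:
    """SimSettings preset for a named trial-budget tier."""
    t = TIERS[tier]
    kw = dict(
        dt=dt, t_end=t.t_end, t_transient=t.t_transient, n_trials=t.n_trials, seed=seed
    )
    kw.update(overrides)
    return SimSettings(**kw)


def log_grid(lo: float = 0.01, hi: float = 5.0, num: int = 25) -> np.ndarray:
    """Logarithmically spaced grid (default noise-intensity axis)."""
    return np.geomspace(lo, hi, num)


def linear_grid(lo: float = 0.01, hi: float = 0.3, num: int = 10) -> np.ndarray:
    """Linearly spaced grid (default coupling axis)."""
    return np.linspace(lo, hi, num)


def _check_grid(grid, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError(f"{name} must be a 1-D grid")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return grid


def _meta(p, c, s, extra=None) -> dict:
    m = {"oscillator": asdict(p), "coupling": asdict(c) if c else None, "simulation": asdict(s)}
    if extra:
        m.update(extra)
    return m


# ---------------------------------------------------------------------------
# single-oscillator coherence resonance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnrSweepResult:
    """β(δ) curve for a single (uncoupled) oscillator."""

    deltas: np.ndarray
    beta_mean: np.ndarray
    beta_sem: np.ndarray
    n_undefined: np.ndarray
    argmax_delta: float
    config: dict = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "snr_sweep": pd.DataFrame(
                {
                    "delta": self.deltas,
                    "beta_mean": self.beta_mean,
                    "beta_sem": self.beta_sem,
                    "n_undefined": self.n_undefined,
                }
            )
        }

    def meta(self) -> dict:
        return dict(self.config or {}, argmax_delta=self.argmax_delta)


def snr_sweep(
    p: OscillatorParams,
    delta_grid,
    s: SimSettings,
    filter_spec: FilterSpec | None = None,
) -> SnrSweepResult:
    """β vs noise intensity for one uncoupled oscillator (λ₀ < 0).

    Per grid point: an ensemble of trials, β per trial from the filtered
    x₁ spectrum on the post-transient window, trial-mean β.  Cells where
    β is undefined for a trial (no interior spectral peak) record the
    failure count; a cell is NaN only if every trial failed.
    """
    if p.lambda0 >= 0:
        raise ValueError("snr_sweep requires the excitable regime (lambda0 < 0)")
    delta_grid = _check_grid(delta_grid, "delta_grid")
    c = CouplingParams(0.0, 0.0)
    spec = filter_spec or FilterSpec()
    means = np.empty(len(delta_grid))
    sems = np.empty(len(delta_grid))
    n_undef = np.zeros(len(delta_grid), dtype=int)
    keep_from = None
    for i, d in enumerate(delta_grid):
        trajs = ensemble(p, c, NoiseParams(d, d), s, substream=(i,))
        if keep_from is None:
            keep_from = trajs[0].times >= s.t_transient
        xs = np.vstack([t.x1 for t in trajs])
        xf = lowpass(xs, s.dt, spec)[:, keep_from]
        betas = []
        for row in xf:
            try:
                betas.append(snr_beta(row, s.dt).beta)
            except UndefinedBetaError:
                n_undef[i] += 1
        if betas:
            b = np.asarray(betas)
            means[i] = b.mean()
            sems[i] = b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else np.nan
        else:
            means[i] = np.nan
            sems[i] = np.nan
    if np.all(np.isnan(means)):
        raise UndefinedBetaError("beta undefined over the whole sweep")
    argmax = float(delta_grid[int(np.nanargmax(means))])
    return SnrSweepResult(
        deltas=delta_grid,
        beta_mean=means,
        beta_sem=sems,
        n_undefined=n_undef,
        argmax_delta=argmax,
        config=_meta(p, c, s, {"filter": asdict(spec)}),
    )


# ---------------------------------------------------------------------------
# synchrony vs one noise axis
# ---------------------------------------------------------------------------


def _ensemble_phases(p, c, n, s, spec, substream) -> list[PhaseSeries]:
    return [extract_phases(t, spec, s.t_transient) for t in ensemble(p, c, n, s, substream)]


def pooled_dphi(p, c, n, s, filter_spec=None, substream=()) -> np.ndarray:
    """Wrapped Δφ samples pooled across all trials of one ensemble."""
    spec = filter_spec or FilterSpec()
    phases = _ensemble_phases(p, c, n, s, spec, substream)
    return np.concatenate([ps.dphi for ps in phases])


@dataclass(frozen=True)
class NoiseSweepResult:
    """|Δφ|, R, ρ versus δ₂ at fixed δ₁."""

    delta2_grid: np.ndarray
    summaries: list[SyncSummary] = field(repr=False, default=None)
    abs_dphi: np.ndarray = None
    R: np.ndarray = None
    rho: np.ndarray = None
    argmin_abs_dphi_delta2: float = None
    argmax_R_delta2: float = None
    argmax_rho_delta2: float = None
    config: dict = field(repr=False, default=None)

    @property
    def optima_within_one_step(self) -> bool:
        """True when the three measures' optima agree to one grid step."""
        g = self.delta2_grid
        idx = [
            int(np.argmin(self.abs_dphi)),
            int(np.argmax(self.R)),
            int(np.argmax(self.rho)),
        ]
        return max(idx) - min(idx) <= 1 and len(g) > 0

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "noise_sweep": pd.DataFrame(
                {
                    "delta2": self.delta2_grid,
                    "abs_dphi": self.abs_dphi,
                    "R": self.R,
                    "rho": self.rho,
                    "abs_dphi_sem": [s.sem_abs_dphi for s in self.summaries],
                    "R_sem": [s.sem_R for s in self.summaries],
                    "rho_sem": [s.sem_rho for s in self.summaries],
                }
            )
        }

    def meta(self) -> dict:
        return dict(
            self.config or {},
            argmin_abs_dphi_delta2=self.argmin_abs_dphi_delta2,
            argmax_R_delta2=self.argmax_R_delta2,
            argmax_rho_delta2=self.argmax_rho_delta2,
        )


def noise_sweep(
    p: OscillatorParams,
    c: CouplingParams,
    fixed_delta1: float,
    delta2_grid,
    s: SimSettings,
    hist: HistogramSpec | None = None,
    filter_spec: FilterSpec | None = None,
) -> NoiseSweepResult:
    """Sweep δ₂ at fixed δ₁ and track all three synchrony measures."""
    if p.lambda0 >= 0:
        raise ValueError("noise_sweep requires the excitable regime (lambda0 < 0)")
    delta2_grid = _check_grid(delta2_grid, "delta2_grid")
    hist = hist or HistogramSpec()
    spec = filter_spec or FilterSpec()
    summaries = []
    for i, d2 in enumerate(delta2_grid):
        phases = _ensemble_phases(p, c, NoiseParams(fixed_delta1, d2), s, spec, (i,))
        summaries.append(trial_summary(phases, hist))
    abs_dphi = np.array([t.mean_abs_dphi for t in summaries])
    R = np.array([t.R for t in summaries])
    rho = np.array([t.rho for t in summaries])
    return NoiseSweepResult(
        delta2_grid=delta2_grid,
        summaries=summaries,
        abs_dphi=abs_dphi,
        R=R,
        rho=rho,
        argmin_abs_dphi_delta2=float(delta2_grid[int(np.argmin(abs_dphi))]),
        argmax_R_delta2=float(delta2_grid[int(np.argmax(R))]),
        argmax_rho_delta2=float(delta2_grid[int(np.argmax(rho))]),
        config=_meta(
            p, c, s,
            {"fixed_delta1": fixed_delta1, "filter": asdict(spec), "histogram": asdict(hist)},
        ),
    )


# ---------------------------------------------------------------------------
# (δ₁, δ₂) heat maps and optimal noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatmapResult:
    """Trial-mean |Δφ| and R over a (δ₁, δ₂) grid.

    ``abs_dphi[i, j]`` corresponds to δ₁ = delta1_grid[i],
    δ₂ = delta2_grid[j].
    """

    delta1_grid: np.ndarray
    delta2_grid: np.ndarray
    abs_dphi: np.ndarray
    R: np.ndarray
    argmin_cell: tuple[int, int]
    local_minima: list[tuple[int, int]]
    config: dict = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        i, j = np.meshgrid(
            np.arange(len(self.delta1_grid)), np.arange(len(self.delta2_grid)), indexing="ij"
        )
        return {
            "heatmap": pd.DataFrame(
                {
                    "delta1": self.delta1_grid[i.ravel()],
                    "delta2": self.delta2_grid[j.ravel()],
                    "abs_dphi": self.abs_dphi.ravel(),
                    "R": self.R.ravel(),
                }
            )
        }

    def meta(self) -> dict:
        return dict(
            self.config or {},
            argmin_cell=list(self.argmin_cell),
            local_minima=[list(c) for c in self.local_minima],
        )


def _smooth3x3(a: np.ndarray) -> np.ndarray:
    """3×3 mean smoothing with edge replication."""
    p = np.pad(a, 1, mode="edge")
    out = np.zeros_like(a, dtype=float)
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            out += p[di : di + a.shape[0], dj : dj + a.shape[1]]
    return out / 9.0


def _local_minima(a: np.ndarray) -> list[tuple[int, int]]:
    """Interior cells strictly below their 4-neighbors after smoothing."""
    sm = _smooth3x3(a)
    mins = []
    for i in range(1, a.shape[0] - 1):
        for j in range(1, a.shape[1] - 1):
            v = sm[i, j]
            if (
                v < sm[i - 1, j] and v < sm[i + 1, j]
                and v < sm[i, j - 1] and v < sm[i, j + 1]
            ):
                mins.append((i, j))
    return mins


def _argmin_cell(values: np.ndarray, d1g: np.ndarray, d2g: np.ndarray) -> tuple[int, int]:
    """Raw grid argmin; ties toward smaller δ₁+δ₂ then smaller δ₁."""
    vmin = np.nanmin(values)
    cand = np.argwhere(values == vmin)
    key = [(d1g[i] + d2g[j], d1g[i]) for i, j in cand]
    return tuple(int(v) for v in cand[int(np.lexsort(np.array(key).T[::-1])[0])])


def noise_heatmap(
    p: OscillatorParams,
    c: CouplingParams,
    delta1_grid,
    delta2_grid,
    s: SimSettings,
    hist: HistogramSpec | None = None,
    filter_spec: FilterSpec | None = None,
) -> HeatmapResult:
    """Trial-mean |Δφ| and R over the full (δ₁, δ₂) grid."""
    delta1_grid = _check_grid(delta1_grid, "delta1_grid")
    delta2_grid = _check_grid(delta2_grid, "delta2_grid")
    hist = hist or HistogramSpec()
    spec = filter_spec or FilterSpec()
    shape = (len(delta1_grid), len(delta2_grid))
    abs_dphi = np.empty(shape)
    R = np.empty(shape)
    for i, d1 in enumerate(delta1_grid):
        for j, d2 in enumerate(delta2_grid):
            phases = _ensemble_phases(p, c, NoiseParams(d1, d2), s, spec, (i, j))
            ts = trial_summary(phases, hist)
            abs_dphi[i, j] = ts.mean_abs_dphi
            R[i, j] = ts.R
    return HeatmapResult(
        delta1_grid=delta1_grid,
        delta2_grid=delta2_grid,
        abs_dphi=abs_dphi,
        R=R,
        argmin_cell=_argmin_cell(abs_dphi, delta1_grid, delta2_grid),
        local_minima=_local_minima(abs_dphi),
        config=_meta(p, c, s, {"filter": asdict(spec), "histogram": asdict(hist)}),
    )


@dataclass(frozen=True)
class OptimalNoiseResult:
    """Argmin of trial-mean |Δφ| over a (δ₁, δ₂) grid and derived ratios."""

    delta1_star: float
    delta2_star: float
    min_abs_dphi: float
    ratio_star: float  # δ₁*/δ₂*, NaN if δ₂* = 0
    sum_star: float
    heatmap: HeatmapResult = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        t = self.heatmap.tables() if self.heatmap else {}
        t["optimal_noise"] = pd.DataFrame(
            [
                {
                    "delta1_star": self.delta1_star,
                    "delta2_star": self.delta2_star,
                    "min_abs_dphi": self.min_abs_dphi,
                    "ratio_star": self.ratio_star,
                    "sum_star": self.sum_star,
                }
            ]
        )
        return t

    def meta(self) -> dict:
        return self.heatmap.meta() if self.heatmap else {}


def optimal_noise(
    p: OscillatorParams,
    c: CouplingParams,
    delta1_grid,
    delta2_grid,
    s: SimSettings,
    hist: HistogramSpec | None = None,
    filter_spec: FilterSpec | None = None,
) -> OptimalNoiseResult:
    """Locate the noise pair (δ₁*, δ₂*) minimizing trial-mean |Δφ|."""
    hm = noise_heatmap(p, c, delta1_grid, delta2_grid, s, hist, filter_spec)
    i, j = hm.argmin_cell
    d1s = float(hm.delta1_grid[i])
    d2s = float(hm.delta2_grid[j])
    return OptimalNoiseResult(
        delta1_star=d1s,
        delta2_star=d2s,
        min_abs_dphi=float(hm.abs_dphi[i, j]),
        ratio_star=d1s / d2s if d2s > 0 else float("nan"),
        sum_star=d1s + d2s,
        heatmap=hm,
    )


# ---------------------------------------------------------------------------
# control-parameter and coupling scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaScanResult:
    """min|Δφ| and optimal-noise sum versus the control parameter λ₀."""

    table: pd.DataFrame
    shallow_slope: float
    steep_slope: float
    shallow_window: tuple[float, float]
    steep_window: tuple[float, float]
    config: dict = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"lambda_scan": self.table}

    def meta(self) -> dict:
        return dict(
            self.config or {},
            shallow_slope=self.shallow_slope,
            steep_slope=self.steep_slope,
            shallow_window=list(self.shallow_window),
            steep_window=list(self.steep_window),
        )


def _window_slope(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    m = (x >= lo) & (x <= hi)
    if m.sum() < 2:
        return float("nan")
    return float(np.polyfit(x[m], y[m], 1)[0])


def lambda_scan(
    p: OscillatorParams,
    lambda0_grid,
    c: CouplingParams,
    delta1_grid,
    delta2_grid,
    s: SimSettings,
    hist: HistogramSpec | None = None,
    filter_spec: FilterSpec | None = None,
    shallow_window: tuple[float, float] = (-1.0, -0.3),
    steep_window: tuple[float, float] = (-0.5, 0.0),
) -> LambdaScanResult:
    """Optimal noise at each λ₀ < 0; slopes of δ₁*+δ₂* in two windows.

    The shallow window captures the far-from-threshold plateau, the
    steep window the drop as λ₀ approaches the bifurcation at 0.
    """
    lambda0_grid = _check_grid(lambda0_grid, "lambda0_grid")
    if np.any(lambda0_grid >= 0):
        raise ValueError("lambda0_grid must lie strictly below 0")
    rows = []
    for k, lam in enumerate(lambda0_grid):
        opt = optimal_noise(
            p.with_lambda0(lam), c, delta1_grid, delta2_grid,
            s.replace(seed=s.seed + k), hist, filter_spec,
        )
        rows.append(
            {
                "lambda0": lam,
                "min_abs_dphi": opt.min_abs_dphi,
                "delta1_star": opt.delta1_star,
                "delta2_star": opt.delta2_star,
                "sum_star": opt.sum_star,
            }
        )
    table = pd.DataFrame(rows)
    x = table["lambda0"].to_numpy()
    y = table["sum_star"].to_numpy()
    return LambdaScanResult(
        table=table,
        shallow_slope=_window_slope(x, y, *shallow_window),
        steep_slope=_window_slope(x, y, *steep_window),
        shallow_window=shallow_window,
        steep_window=steep_window,
        config=_meta(p, c, s),
    )


@dataclass(frozen=True)
class CouplingScanResult:
    """Optimal-noise ratio and abs.min|Δφ| maps over a (d₁, d₂) grid."""

    d1_grid: np.ndarray
    d2_grid: np.ndarray
    ratio_star: np.ndarray
    min_abs_dphi: np.ndarray
    sum_star: np.ndarray
    mean_ratio_d1_lt_d2: float
    mean_ratio_d1_gt_d2: float
    config: dict = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        i, j = np.meshgrid(
            np.arange(len(self.d1_grid)), np.arange(len(self.d2_grid)), indexing="ij"
        )
        return {
            "coupling_scan": pd.DataFrame(
                {
                    "d1": self.d1_grid[i.ravel()],
                    "d2": self.d2_grid[j.ravel()],
                    "ratio_star": self.ratio_star.ravel(),
                    "min_abs_dphi": self.min_abs_dphi.ravel(),
                    "sum_star": self.sum_star.ravel(),
                }
            )
        }

    def meta(self) -> dict:
        return dict(
            self.config or {},
            mean_ratio_d1_lt_d2=self.mean_ratio_d1_lt_d2,
            mean_ratio_d1_gt_d2=self.mean_ratio_d1_gt_d2,
        )


def coupling_scan(
    p: OscillatorParams,
    d1_grid,
    d2_grid,
    delta1_grid,
    delta2_grid,
    s: SimSettings,
    hist: HistogramSpec | None = None,
    filter_spec: FilterSpec | None = None,
) -> CouplingScanResult:
    """Optimal noise per coupling pair; summaries over the two triangles."""
    d1_grid = _check_grid(d1_grid, "d1_grid")
    d2_grid = _check_grid(d2_grid, "d2_grid")
    shape = (len(d1_grid), len(d2_grid))
    ratio = np.empty(shape)
    mind = np.empty(shape)
    sums = np.empty(shape)
    for i, d1 in enumerate(d1_grid):
        for j, d2 in enumerate(d2_grid):
            opt = optimal_noise(
                p, CouplingParams(d1, d2), delta1_grid, delta2_grid,
                s.replace(seed=s.seed + i * len(d2_grid) + j), hist, filter_spec,
            )
            ratio[i, j] = opt.ratio_star
            mind[i, j] = opt.min_abs_dphi
            sums[i, j] = opt.sum_star
    ii, jj = np.meshgrid(d1_grid, d2_grid, indexing="ij")
    lower = ii < jj  # d1 < d2
    upper = ii > jj
    return CouplingScanResult(
        d1_grid=d1_grid,
        d2_grid=d2_grid,
        ratio_star=ratio,
        min_abs_dphi=mind,
        sum_star=sums,
        mean_ratio_d1_lt_d2=float(np.nanmean(ratio[lower])) if lower.any() else float("nan"),
        mean_ratio_d1_gt_d2=float(np.nanmean(ratio[upper])) if upper.any() else float("nan"),
        config=_meta(p, None, s),
    )
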