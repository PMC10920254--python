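import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

from motifsync import (
    CouplingParams,
    IntegrationBlowUpError,
    NoiseParams,
    OscillatorParams,
    SimSettings,
    ensemble,
    integrate_deterministic,
    limit_cycle_radius,
    simulate,
)
from motifsync.sde import read_trajectory, write_trajectory

NO_NOISE = NoiseParams(0.0, 0.0)
UNCOUPLED = CouplingParams(0.0, 0.0)


class TestSimulate:
    def test_seeded_determinism_bit_identical(self, paper_params, uneven_coupling):
        s = SimSettings(t_end=20, t_transient=5, n_trials=1, seed=11)
        n = NoiseParams(0.05, 0.95)
        a = simulate(paper_params, uneven_coupling, n, s)
        b = simulate(paper_params, uneven_coupling, n, s)
        np.testing.assert_array_equal(a.x1, b.x1)
        np.testing.assert_array_equal(a.y2, b.y2)

    def test_excitable_deterministic_decays_to_origin(self, paper_params):
        s = SimSettings(t_end=50, t_transient=10, n_trials=1, seed=0)
        traj = simulate(paper_params, UNCOUPLED, NO_NOISE, s)
        assert np.linalg.norm(traj.terminal_state()) < 1e-3

    def test_oscillatory_deterministic_reaches_limit_cycle(self):
        p = OscillatorParams(lambda0=0.8)
        s = SimSettings(t_end=100, t_transient=10, n_trials=1, seed=0)
        traj = simulate(p, UNCOUPLED, NO_NOISE, s, ic=[0.3, 0.0, 0.0, 0.3])
        rstar = limit_cycle_radius(p)
        r_end = np.hypot(traj.x1[-1], traj.y1[-1])
        assert r_end == pytest.approx(rstar, rel=0.01)

    def test_time_grid_uniform(self, paper_params):
        s = SimSettings(t_end=10, t_transient=1, n_trials=1, seed=3)
        traj = simulate(paper_params, UNCOUPLED, NoiseParams(0.1, 0.1), s)
        assert np.all(np.abs(np.diff(traj.times) - s.dt) < 1e-12)

    def test_blowup_raises_with_step_index(self):
        # destabilized radial polynomial plus a huge step forces divergence
        p = OscillatorParams(lambda0=1.0, alpha=1.0, gamma=1.0)
        s = SimSettings(dt=1.0, t_end=50, t_transient=0, n_trials=1, seed=0)
        with pytest.raises(IntegrationBlowUpError, match="step"):
            simulate(p, UNCOUPLED, NO_NOISE, s, ic=[1.0, 0.0, 0.0, 0.0])

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            SimSettings(dt=-1.0)

    def test_noise_only_enters_x(self, paper_params):
        """With δ₂ = 0 and d₂ = 0, oscillator 2 is fully deterministic given its IC."""
        c = CouplingParams(0.3, 0.0)
        s = SimSettings(t_end=20, t_transient=5, n_trials=1)
        ic = [0.1, -0.05, 0.08, 0.02]
        a = simulate(paper_params, c, NoiseParams(1.0, 0.0), s.replace(seed=1), ic=ic)
        b = simulate(paper_params, c, NoiseParams(1.0, 0.0), s.replace(seed=2), ic=ic)
        # different noise streams change oscillator 1 but not oscillator 2
        assert not np.array_equal(a.x1, b.x1)
        np.testing.assert_array_equal(a.x2, b.x2)
        np.testing.assert_array_equal(a.y2, b.y2)


class TestEnsemble:
    def test_singleton_matches_simulate_substream_zero(self, paper_params, uneven_coupling):
        s = SimSettings(t_end=10, t_transient=1, n_trials=1, seed=9)
        n = NoiseParams(0.05, 0.95)
        ens = ensemble(paper_params, uneven_coupling, n, s)
        solo = simulate(paper_params, uneven_coupling, n, s, trial_index=0)
        np.testing.assert_array_equal(ens[0].x1, solo.x1)
        np.testing.assert_array_equal(ens[0].y2, solo.y2)

    def test_trials_match_their_substreams_bitwise(self, paper_params, uneven_coupling):
        s = SimSettings(t_end=10, t_transient=1, n_trials=4, seed=9)
        n = NoiseParams(0.05, 0.95)
        ens = ensemble(paper_params, uneven_coupling, n, s)
        for k in (1, 3):
            solo = simulate(paper_params, uneven_coupling, n, s, trial_index=k)
            np.testing.assert_array_equal(ens[k].x1, solo.x1)

    def test_same_seed_reproduces_different_seed_differs(self, paper_params):
        s = SimSettings(t_end=5, t_transient=1, n_trials=3, seed=4)
        n = NoiseParams(0.2, 0.2)
        a = ensemble(paper_params, UNCOUPLED, n, s)
        b = ensemble(paper_params, UNCOUPLED, n, s)
        c = ensemble(paper_params, UNCOUPLED, n, s.replace(seed=5))
        np.testing.assert_array_equal(a[2].x1, b[2].x1)
        assert not np.array_equal(a[0].x1, c[0].x1)

    def test_noise_free_trials_differ_only_via_ics(self, paper_params):
        s = SimSettings(t_end=5, t_transient=1, n_trials=3, seed=4)
        ens = ensemble(paper_params, UNCOUPLED, NO_NOISE, s)
        # dynamics are deterministic: trajectories from distinct ICs differ,
        # but each decays toward the origin monotonically in radius envelope
        assert not np.array_equal(ens[0].x1, ens[1].x1)
        for tr in ens:
            r0 = np.hypot(tr.x1[0], tr.y1[0])
            r_end = np.hypot(tr.x1[-1], tr.y1[-1])
            assert r_end < max(r0, 1e-6)

    def test_ensemble_mean_near_zero_in_excitable_regime(self, paper_params):
        s = SimSettings(t_end=60, t_transient=20, n_trials=24, seed=8)
        ens = ensemble(paper_params, UNCOUPLED, NoiseParams(0.5, 0.5), s)
        pooled = np.concatenate([tr.x1[tr.times >= 20] for tr in ens])
        # symmetric dynamics about the origin: mean of x vanishes within MC error
        assert abs(pooled.mean()) < 3 * pooled.std() / np.sqrt(len(ens) * 40)


class TestDeterministicOracle:
    def test_origin_stays_at_origin(self, paper_params):
        s = SimSettings(t_end=10, t_transient=1, n_trials=1)
        traj = integrate_deterministic(paper_params, UNCOUPLED, [0, 0, 0, 0], s)
        assert np.all(np.abs(traj.x1) < 1e-12)

    def test_symmetric_ic_stays_symmetric(self, paper_params):
        s = SimSettings(t_end=30, t_transient=1, n_trials=1)
        c = CouplingParams(0.2, 0.2)
        traj = integrate_deterministic(paper_params, c, [0.1, -0.2, 0.1, -0.2], s)
        assert np.max(np.abs(traj.x1 - traj.x2)) < 1e-9
        assert np.max(np.abs(traj.y1 - traj.y2)) < 1e-9

    def test_euler_error_first_order_in_dt(self):
        """Noise-free Euler error vs the RK oracle roughly halves with dt."""
        p = OscillatorParams(lambda0=0.8)
        c = CouplingParams(0.1, 0.05)
        ic = [0.5, 0.0, 0.0, 0.5]
        errs = []
        for dt in (0.02, 0.01):
            s = SimSettings(dt=dt, t_end=10, t_transient=1, n_trials=1)
            em = simulate(p, c, NO_NOISE, s, ic=ic)
            ref = integrate_deterministic(p, c, ic, s)
            errs.append(np.max(np.abs(em.x1 - ref.x1)))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 3.0


def test_linear_regime_stationary_variance_matches_lyapunov(rng):
    """Simulated Var(x) matches the closed-form stationary covariance within 5%.

    For the linear SDE (α = γ = 0) dz = A z dt + B dW with
    A = [[λ₀, −ω₀], [ω₀, λ₀]] and noise only on x, the stationary
    covariance Σ solves A Σ + Σ Aᵀ + diag(δ², 0) = 0.
    """
    lam0, om0, delta = -0.5, 2.0, 0.3
    A = np.array([[lam0, -om0], [om0, lam0]])
    Q = np.diag([delta**2, 0.0])
    sigma = solve_continuous_lyapunov(A, -Q)
    p = OscillatorParams(lambda0=lam0, alpha=0.0, gamma=0.0)
    s = SimSettings(t_end=500, t_transient=50, n_trials=8, seed=123)
    ens = ensemble(p, UNCOUPLED, NoiseParams(delta, delta), s)
    pooled = np.concatenate([tr.x1[tr.times >= 50] for tr in ens])
    assert pooled.var() == pytest.approx(sigma[0, 0], rel=0.05)


def test_trajectory_roundtrip(tmp_path, paper_params):
    s = SimSettings(t_end=5, t_transient=1, n_trials=1, seed=2)
    traj = simulate(paper_params, CouplingParams(0.3, 0.01), NoiseParams(0.1, 0.2), s)
    prefix = str(tmp_path / "traj")
    write_trajectory(traj, prefix)
    back = read_trajectory(prefix)
    np.testing.assert_allclose(back.x1, traj.x1)
    np.testing.assert_allclose(back.times, traj.times)
    assert back.config == traj.config
    assert back.seed == traj.seed
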