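"""Run-and-tumble simulator: internal dynamics, turning statistics, dispersal."""

import numpy as np
import pytest

from chemoscale.agents import (
    AgentParams,
    Cell,
    draw_new_velocity,
    run_statistics,
    simulate_population,
    step_internal,
    turning_rate,
)
from chemoscale.cartoon import CartoonParams, StimulusProtocol, integrate_cartoon
from chemoscale.pks import coefficients_from_cell_params, consistency_b_from_turning_rate


@pytest.fixture
def params() -> AgentParams:
    return AgentParams(dim=1)  # s0=20, lambda0=1, gamma0=1, t_e=0.1, t_a=5


class TestInternalDynamics:
    def test_rest_state_unchanged(self, params):
        cell = Cell(x=np.zeros(1), v=np.array([20.0]))
        step_internal(cell, 0.0, 0.05, params)
        assert cell.y1 == 0.0 and cell.y2 == 0.0

    def test_adapts_to_constant_signal(self, params):
        cell = Cell(x=np.zeros(1), v=np.array([20.0]))
        for _ in range(int(20 * params.t_a / 0.05)):
            step_internal(cell, 2.0, 0.05, params)
        assert abs(cell.y1) < 1e-8
        assert cell.y2 == pytest.approx(2.0, rel=1e-8)

    def test_matches_cartoon_integrator(self, params):
        """The agent's internal update and the excitation-adaptation
        integrator are the same linear system."""
        cp = CartoonParams(tau_e=params.t_e, tau_a=params.t_a)
        traj = integrate_cartoon(cp, StimulusProtocol.step(1.5), dt=0.02, t_end=2.0)
        cell = Cell(x=np.zeros(1), v=np.array([20.0]))
        for _ in range(100):
            step_internal(cell, 1.5, 0.02, params)
        assert cell.y1 == pytest.approx(traj["u1"].iloc[-1], abs=1e-12)
        assert cell.y2 == pytest.approx(traj["u2"].iloc[-1], abs=1e-12)


class TestTurningRate:
    def test_baseline_and_limits(self, params):
        assert turning_rate(0.0, params) == params.lambda0
        assert turning_rate(1e12, params) == pytest.approx(0.0, abs=1e-9)
        assert turning_rate(-1e12, params) == pytest.approx(2 * params.lambda0, abs=1e-9)

    def test_bounded(self, params):
        y = np.linspace(-50, 50, 1001)
        lam = turning_rate(y, params)
        assert np.all(lam >= 0.0) and np.all(lam <= 2 * params.lambda0)


class TestTurningKernel:
    def test_1d_uniform_sign(self, params):
        rng = np.random.default_rng(7)
        draws = np.array(
            [draw_new_velocity(rng, np.array([20.0]), params)[0] for _ in range(10_000)]
        )
        assert np.all(np.abs(draws) == params.s0)
        assert np.mean(draws > 0) == pytest.approx(0.5, abs=0.015)

    def test_2d_isotropic(self):
        p = AgentParams(dim=2)
        rng = np.random.default_rng(7)
        incoming = np.array([p.s0, 0.0])
        vs = np.array([draw_new_velocity(rng, incoming, p) for _ in range(10_000)])
        assert np.allclose(np.linalg.norm(vs, axis=1), p.s0, atol=1e-9)
        cosines = vs[:, 0] / p.s0
        assert abs(np.mean(cosines)) < 0.02


class TestSimulation:
    def test_dt_too_large_refused(self, params):
        with pytest.raises(ValueError, match="dt"):
            simulate_population(params, 10, 1.0, dt=0.05)

    def test_determinism(self, params):
        a = simulate_population(params, 50, 10.0, dt=0.02, seed=42)
        b = simulate_population(params, 50, 10.0, dt=0.02, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.run_intervals, b.run_intervals)

    def test_speed_is_constant(self, params):
        traj = simulate_population(params, 20, 5.0, dt=0.02, seed=0)
        step = np.diff(traj.positions[:, :, 0], axis=0)
        dt_sample = traj.times[1] - traj.times[0]
        # each sampled displacement is a sum of +-s0*dt moves
        assert np.max(np.abs(step)) <= params.s0 * dt_sample + 1e-9

    def test_mean_run_interval(self, params):
        traj = simulate_population(params, 300, 100.0, dt=0.005, seed=3)
        stats = run_statistics(traj)
        assert stats.n_events >= 10_000
        assert stats.mean_run == pytest.approx(1.0 / params.lambda0, rel=0.02)

    def test_diffusion_matches_velocity_jump_formula(self, params):
        """MSD-based diffusivity -> s0^2/(N*lambda0) for the uniform kernel."""
        traj = simulate_population(params, 4000, 100.0, dt=0.005, seed=5, sample_every=20)
        stats = run_statistics(traj)
        expected = params.s0**2 / (params.dim * params.lambda0)
        assert stats.diffusion == pytest.approx(expected, rel=0.05)

    def test_density_uniform_on_periodic_domain(self, params):
        from scipy.stats import chisquare

        traj = simulate_population(
            params, 2000, 50.0, dt=0.02, seed=11, domain=[2000.0], bc="periodic"
        )
        x_final = traj.positions[-1, :, 0]
        counts, _ = np.histogram(x_final, bins=10, range=(0, 2000.0))
        assert chisquare(counts).pvalue > 0.01

    def test_insufficient_events_error(self, params):
        traj = simulate_population(params, 5, 2.0, dt=0.02, seed=0)
        with pytest.raises(ValueError, match="insufficient"):
            run_statistics(traj)

    def test_angular_drift_curves_clockwise(self):
        """With omega > 0 and rare tumbles, headings rotate at -omega."""
        p = AgentParams(dim=2, lambda0=0.01, omega=0.5, t_e=0.1, t_a=5.0)
        traj = simulate_population(p, 200, 10.0, dt=0.02, seed=1)
        dtheta = traj.headings[-1] - traj.headings[0]
        rate = np.median(dtheta) / traj.times[-1]
        assert rate == pytest.approx(-0.5, rel=1e-6)


class TestChemotacticDrift:
    def test_drift_matches_continuum_sensitivity(self):
        """In a shallow static linear gradient the population drifts
        up-gradient at chi * dS/dx, with chi from the microscopic formula."""
        params = AgentParams(dim=1)
        grad = 2e-3
        signal = lambda x, t: grad * x[:, 0]
        traj = simulate_population(
            params, 8000, 400.0, dt=0.02, seed=9, signal=signal, sample_every=100
        )
        b = consistency_b_from_turning_rate(params)
        chi = coefficients_from_cell_params(
            params.s0, params.lambda0, b, params.t_a, params.t_e, 1
        ).chi
        expected_drift = chi * grad
        mean_x = traj.positions[:, :, 0].mean(axis=1)
        # endpoint-difference estimator (optimal for a drifting random walk);
        # start past the adaptation transient
        i0 = int(np.argmin(np.abs(traj.times - 20.0)))
        drift = (mean_x[-1] - mean_x[i0]) / (traj.times[-1] - traj.times[i0])
        assert drift == pytest.approx(expected_drift, rel=0.10)

    def test_validates_gradient_sign(self):
        """Drift is up-gradient for an attractant (positive gradient)."""
        params = AgentParams(dim=1)
        signal = lambda x, t: 2e-3 * x[:, 0]
        traj = simulate_population(
            params, 2000, 100.0, dt=0.02, seed=2, signal=signal, sample_every=50
        )
        assert traj.positions[-1, :, 0].mean() > traj.positions[0, :, 0].mean()
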